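"""Core math: windowing, autocorrelation, bandwidths, ρ, and the fast map.

Closed-form oracles used below (a = window width, Δ = pitch):

* linear ramp t = c(x − x̄):  Σ(x−x̄)² = a(a²−1)/12·Δ² per row, gradient
  exactly c everywhere, hence τ² = 12/((a²−1)Δ²) and ρ = 2πΔ√((a²−1)/12);
* one-period sinusoid on a circular patch: central differences scale the
  derivative by sin(kΔ)/(kΔ), hence τ = sin(2π/a)/Δ and ρ = 2πΔ/sin(2π/a);
* circular spatial ↔ matched spectral bandwidth are the same number by
  Parseval and the diagonalization of circular convolution.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasecorr import (
    PhaseImage,
    bandwidth_spatial,
    bandwidth_spectral,
    correlation_length,
    correlation_length_map,
    local_zero_mean,
    patch_autocorrelation,
)
from phasecorr.corrlength import LocalPatch, WindowSpec

from conftest import naive_length_map, random_patch_image


def make_patch(seed: int, a: int = 64, pitch: float = 1.0) -> LocalPatch:
    rng = np.random.default_rng(seed)
    t = rng.standard_normal((a, a))
    return LocalPatch(t=t - t.mean(), pitch=pitch)


def ramp_patch(a: int = 64, pitch: float = 1.0, c: float = 0.7) -> LocalPatch:
    cols = (np.arange(a) - (a - 1) / 2.0) * pitch
    t = np.broadcast_to(c * cols, (a, a)).copy()
    return LocalPatch(t=t, pitch=pitch)


def sinusoid_patch(a: int = 64, pitch: float = 1.0) -> LocalPatch:
    x = np.arange(a)
    t = np.broadcast_to(np.sin(2.0 * np.pi * x / a), (a, a)).copy()
    return LocalPatch(t=t - t.mean(), pitch=pitch)


# ---------------------------------------------------------------------------
# local_zero_mean
# ---------------------------------------------------------------------------


def test_constant_window_maps_to_zeros():
    img = PhaseImage(np.full((16, 16), 2.0), pitch=1.0)
    patch = local_zero_mean(img, WindowSpec(a=8), (8, 8))
    np.testing.assert_array_equal(patch.t, np.zeros((8, 8)))


def test_mean_removal_arithmetic():
    values = np.arange(16.0).reshape(4, 4)  # mean 7.5
    img = PhaseImage(values, pitch=1.0)
    patch = local_zero_mean(img, WindowSpec(a=4), (2, 2))
    np.testing.assert_allclose(patch.t, values - 7.5, atol=1e-14)


@pytest.mark.parametrize("seed", range(5))
def test_patch_mean_is_zero_within_tolerance(seed):
    img = random_patch_image(seed, n=80)
    patch = local_zero_mean(img, WindowSpec(a=64), (40, 40))
    assert abs(patch.t.mean()) <= 1e-12 * np.abs(patch.t).max()


@pytest.mark.parametrize("center", [(0, 40), (40, 0), (79, 40), (31, 31)])
def test_footprint_crossing_border_raises(center):
    img = random_patch_image(0, n=80)
    with pytest.raises(ValueError, match="crosses the border"):
        local_zero_mean(img, WindowSpec(a=64), center)


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def test_impulse_autocorrelation_is_squared_impulse_at_zero_lag():
    a, v = 8, 3.0
    t = np.zeros((a, a))
    t[2, 5] = v  # raw-array oracle input: mean adjustment deliberately absent
    gamma = patch_autocorrelation(t).gamma
    assert gamma.shape == (2 * a - 1, 2 * a - 1)
    assert gamma[a - 1, a - 1] == pytest.approx(v * v, rel=1e-12)
    assert np.sum(np.abs(gamma) > 1e-9) == 1


@pytest.mark.parametrize("seed", range(3))
def test_zero_lag_equals_total_energy_and_lag_inversion_symmetry(seed):
    patch = make_patch(seed, a=32)
    ac = patch_autocorrelation(patch)
    assert ac.zero_lag == pytest.approx(patch.energy, rel=1e-12)
    np.testing.assert_array_equal(ac.gamma, ac.gamma[::-1, ::-1])


# ---------------------------------------------------------------------------
# bandwidths
# ---------------------------------------------------------------------------


def test_zero_patch_is_degenerate_everywhere():
    patch = LocalPatch(t=np.zeros((16, 16)), pitch=1.0)
    assert bandwidth_spectral(patch).degenerate
    assert bandwidth_spatial(patch).degenerate
    assert np.isnan(correlation_length(patch))


@pytest.mark.parametrize("pitch", [1.0, 0.125])
def test_sinusoid_matched_spectral_bandwidth_closed_form(pitch):
    a = 64
    patch = sinusoid_patch(a=a, pitch=pitch)
    tau = bandwidth_spectral(patch, matched=True).tau
    assert tau == pytest.approx(np.sin(2 * np.pi / a) / pitch, rel=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_parseval_equivalence_spatial_circular_vs_matched_spectral(seed):
    patch = make_patch(seed, a=64, pitch=0.25)
    tau_sp = bandwidth_spatial(patch, circular=True).tau
    tau_fr = bandwidth_spectral(patch, matched=True).tau
    assert tau_sp == pytest.approx(tau_fr, rel=1e-9)


@pytest.mark.parametrize("a,pitch", [(64, 1.0), (32, 0.125)])
def test_ramp_bandwidth_closed_form(a, pitch):
    patch = ramp_patch(a=a, pitch=pitch)
    tau2 = bandwidth_spatial(patch, circular=False).tau ** 2
    assert tau2 == pytest.approx(12.0 / ((a * a - 1) * pitch * pitch), rel=1e-12)


# ---------------------------------------------------------------------------
# correlation_length
# ---------------------------------------------------------------------------


def test_ramp_length_closed_form():
    a, pitch = 64, 1.0
    rho = correlation_length(ramp_patch(a=a, pitch=pitch))
    assert rho == pytest.approx(2 * np.pi * np.sqrt((a * a - 1) / 12.0) * pitch, rel=1e-12)


def test_sinusoid_length_closed_form_circular():
    a, pitch = 64, 1.0
    rho = correlation_length(sinusoid_patch(a=a, pitch=pitch), circular=True)
    assert rho == pytest.approx(2 * np.pi * pitch / np.sin(2 * np.pi / a), rel=1e-9)


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("circular", [False, True])
def test_product_law_rho_times_tau_is_2pi(seed, circular):
    patch = make_patch(seed, pitch=0.5)
    rho = correlation_length(patch, circular=circular)
    tau = bandwidth_spatial(patch, circular=circular).tau
    assert rho * tau == pytest.approx(2 * np.pi, rel=1e-12)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    c=st.floats(min_value=-1e3, max_value=1e3).filter(lambda v: abs(v) > 1e-6),
    s=st.floats(min_value=1e-2, max_value=1e2),
)
def test_scale_equivariance_of_length(c, s):
    """ρ ignores phase amplitude; scaling the pitch by s scales ρ by s."""
    base = make_patch(42, a=32, pitch=0.5)
    rho = correlation_length(base)
    scaled_values = LocalPatch(t=base.t * c, pitch=base.pitch)
    assert correlation_length(scaled_values) == pytest.approx(rho, rel=1e-9)
    scaled_pitch = LocalPatch(t=base.t, pitch=base.pitch * s)
    assert correlation_length(scaled_pitch) == pytest.approx(rho * s, rel=1e-9)


# ---------------------------------------------------------------------------
# correlation_length_map (fast path)
# ---------------------------------------------------------------------------


def test_constant_image_has_no_valid_centers():
    img = PhaseImage(np.full((96, 96), 1.5), pitch=1.0)
    m = correlation_length_map(img, WindowSpec(a=64))
    assert not m.valid.any()
    assert np.isnan(m.lengths).all()


def test_image_smaller_than_window_raises():
    img = PhaseImage(np.zeros((32, 96)), pitch=1.0)
    with pytest.raises(ValueError, match="smaller than"):
        correlation_length_map(img, WindowSpec(a=64))


def test_border_centers_are_invalid(smooth_image_128):
    m = correlation_length_map(smooth_image_128, WindowSpec(a=64))
    a = 64
    assert not m.valid[: a // 2, :].any()
    assert not m.valid[:, : a // 2].any()
    # for even a the footprint of center r spans r−a/2 … r+a/2−1, so the
    # trailing invalid margin is one row narrower than the leading one
    assert not m.valid[-(a // 2 - 1) :, :].any()
    assert m.valid[a // 2, a // 2] and m.valid[128 - a // 2, 128 - a // 2]


def test_fast_path_matches_naive_per_window_evaluation(smooth_image_128):
    window = WindowSpec(a=64)
    m = correlation_length_map(smooth_image_128, window)
    oracle = naive_length_map(smooth_image_128, window)
    got = m.lengths[32 : 32 + oracle.shape[0], 32 : 32 + oracle.shape[1]]
    np.testing.assert_allclose(got, oracle, rtol=1e-9)


def test_stride_subsamples_the_center_grid(smooth_image_128):
    dense = correlation_length_map(smooth_image_128, WindowSpec(a=64, stride=1))
    coarse = correlation_length_map(smooth_image_128, WindowSpec(a=64, stride=8))
    assert int(coarse.valid.sum()) < int(dense.valid.sum())
    rr, cc = np.nonzero(coarse.valid)
    assert ((rr - 32) % 8 == 0).all() and ((cc - 32) % 8 == 0).all()
    np.testing.assert_allclose(
        coarse.lengths[coarse.valid], dense.lengths[coarse.valid], rtol=1e-12
    )


def test_map_scale_equivariance(smooth_image_128):
    window = WindowSpec(a=64, stride=4)
    m1 = correlation_length_map(smooth_image_128, window)
    m2 = correlation_length_map(
        PhaseImage(smooth_image_128.values * -3.7, pitch=smooth_image_128.pitch), window
    )
    m3 = correlation_length_map(
        PhaseImage(smooth_image_128.values, pitch=smooth_image_128.pitch * 2.0), window
    )
    np.testing.assert_allclose(m2.lengths[m1.valid], m1.lengths[m1.valid], rtol=1e-9)
    np.testing.assert_allclose(m3.lengths[m1.valid], 2.0 * m1.lengths[m1.valid], rtol=1e-9)


def test_mean_length_increases_with_field_correlation_parameter():
    """Mean interior ρ is strictly increasing in σ across {1, 2, 3, 4} px."""
    means = []
    for sigma in (1.0, 2.0, 3.0, 4.0):
        img = random_patch_image(seed=77, n=192, sigma=sigma)
        m = correlation_length_map(img, WindowSpec(a=64, stride=8))
        interior = m.lengths[40:152, 40:152]
        vals = interior[np.isfinite(interior)]
        assert vals.size >= 25
        means.append(vals.mean())
    assert np.all(np.diff(means) > 0), means
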