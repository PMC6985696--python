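"""Local spatial autocorrelation length of a phase image.

The local autocorrelation length ρ(x′, y′) measures, at every position of
a sliding window, how far phase fluctuations stay correlated.  Within an
a×a window centered at (x′, y′) the mean-removed phase

    t(x, y; x′, y′) = ϕ(x, y) − ⟨ϕ⟩_window

has an autocorrelation Γ = t ⊗ t whose width is ρ.  Rather than measuring
that width directly (two FFTs per window), ρ is obtained from the root
second moment of the window's spatial power spectrum — the spectral
bandwidth

    τ²(x′, y′) = Σ (k_x² + k_y²) |T|² / Σ |T|²,

which by the differentiation property of the Fourier transform and
Parseval's theorem is the purely spatial ratio

    τ² = Σ (|∂t/∂x|² + |∂t/∂y|²) / Σ |t|²,

with ρ·τ = 2π taken as the operational definition of ρ:

    ρ = 2π sqrt( Σ|t|² / Σ(|∂t/∂x|² + |∂t/∂y|²) ).

Because the gradient of the subtracted window mean vanishes and the
numerator obeys Σt² = Σϕ² − (Σϕ)²/a², the whole dense map factorizes
into three global images (ϕ, ϕ², |∇ϕ|²) plus O(1) windowed sums via
summed-area tables — no per-window transforms at all.  That fast path is
:func:`correlation_length_map`; the per-patch functions below serve as
its independently-computed building blocks and oracles.

Discretization choices (documented, since they shape the numbers):

* derivatives are central differences with physical spacing Δ = pitch,
  one-sided at non-circular edges (``numpy.gradient`` semantics);
* the map treats the window as a *restriction* of the image — gradients
  are taken once on the full image, so the rim of a window carries true
  central differences and the artificial edge of the excerpt contributes
  no spurious gradient energy;
* a window whose gradient energy falls below
  ``1e-12 · a² · max(1, var(ϕ))`` is degenerate: flagged invalid, never
  clamped to a fake length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .images import CorrelationLengthMap, PhaseImage

__all__ = [
    "WindowSpec",
    "LocalPatch",
    "Autocorrelogram",
    "BandwidthValue",
    "local_zero_mean",
    "patch_autocorrelation",
    "bandwidth_spectral",
    "bandwidth_spatial",
    "correlation_length",
    "correlation_length_map",
]

#: Relative floor (times a²·max(1, energy scale)) below which a window is
#: treated as having no usable fluctuation energy.
ENERGY_REL_TOL = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Square sliding-window geometry.

    ``a`` is the window width in pixels (default 64, i.e. 8 μm at the
    default 0.125 μm/pixel pitch); ``stride`` the spacing of evaluated
    centers.  For even ``a`` the footprint of center (r, c) spans rows
    ``r − a/2 … r + a/2 − 1`` and likewise columns; windows that are not
    fully inside the image are never evaluated (valid-only policy).
    """

    a: int = 64
    stride: int = 1

    def __post_init__(self) -> None:
        if int(self.a) < 4:
            raise ValueError(f"window width must be ≥ 4 pixels, got {self.a}")
        if int(self.stride) < 1:
            raise ValueError(f"stride must be ≥ 1, got {self.stride}")
        object.__setattr__(self, "a", int(self.a))
        object.__setattr__(self, "stride", int(self.stride))

    def start(self, center: int) -> int:
        """First row/column of the footprint for a center coordinate."""
        return center - self.a // 2


@dataclass(frozen=True)
class LocalPatch:
    """An a×a mean-removed window excerpt t(x, y; x′, y′), radians."""

    t: np.ndarray
    pitch: float
    center: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError(f"patch must be square 2-D, got shape {t.shape}")
        if not np.isfinite(t).all():
            raise ValueError("patch contains non-finite values")
        if not (self.pitch > 0):
            raise ValueError("pitch must be > 0")
        peak = float(np.max(np.abs(t)))
        if abs(float(t.mean())) > 1e-12 * peak:
            raise ValueError("patch is not zero-mean to within 1e-12 of its peak")
        object.__setattr__(self, "t", t)

    @property
    def a(self) -> int:
        return self.t.shape[0]

    @property
    def energy(self) -> float:
        """Total squared fluctuation energy Σt² (rad²)."""
        return float(np.sum(self.t * self.t))


@dataclass(frozen=True)
class Autocorrelogram:
    """Full 2-D autocorrelation Γ of a patch; lag (0, 0) at the grid center."""

    gamma: np.ndarray
    pitch: float

    @property
    def zero_lag(self) -> float:
        n = self.gamma.shape[0] // 2
        return float(self.gamma[n, n])


@dataclass(frozen=True)
class BandwidthValue:
    """Spectral bandwidth τ (rad/μm); degenerate when the patch has no energy."""

    tau: float
    degenerate: bool


def _energy_floor(a: int, scale: float) -> float:
    return ENERGY_REL_TOL * a * a * max(1.0, scale)


def local_zero_mean(
    phase: PhaseImage, window: WindowSpec, center: tuple[int, int]
) -> LocalPatch:
    """Extract the a×a window at ``center`` and remove its arithmetic mean.

    Raises if the footprint crosses the image border (valid-only policy).
    """
    a = window.a
    r0, c0 = window.start(center[0]), window.start(center[1])
    h, w = phase.shape
    if r0 < 0 or c0 < 0 or r0 + a > h or c0 + a > w:
        raise ValueError(
            f"window footprint [{r0}:{r0 + a}, {c0}:{c0 + a}] for center "
            f"{center} crosses the border of a {h}×{w} image"
        )
    block = phase.values[r0 : r0 + a, c0 : c0 + a].astype(np.float64)
    return LocalPatch(t=block - block.mean(), pitch=phase.pitch, center=center)


def patch_autocorrelation(patch: LocalPatch | np.ndarray) -> Autocorrelogram:
    """Full (2a−1)×(2a−1) discrete autocorrelation Γ = t ⊗ t (zero-padded).

    Γ at zero lag equals Σt², and Γ(u, v) = Γ(−u, −v) for the real field.
    A raw square array is accepted as well (mean removal not enforced),
    which is useful for impulse-response oracles.
    """
    t = patch.t if isinstance(patch, LocalPatch) else np.asarray(patch, dtype=np.float64)
    pitch = patch.pitch if isinstance(patch, LocalPatch) else 1.0
    gamma = signal.correlate(t, t, mode="full", method="fft")
    # fft path leaves ~1e-13-scale asymmetries; symmetrize exactly
    gamma = 0.5 * (gamma + gamma[::-1, ::-1])
    return Autocorrelogram(gamma=gamma, pitch=pitch)


def bandwidth_spectral(patch: LocalPatch, matched: bool = False) -> BandwidthValue:
    """Bandwidth τ from the discrete power spectrum of the patch.

    With ``matched=False`` the second moment uses the true squared angular
    frequency k_x² + k_y².  With ``matched=True`` it uses the squared
    transfer-function magnitude of the circular central-difference
    operator, (sin(k Δ)/Δ)², which makes this an exact frequency-domain
    twin of :func:`bandwidth_spatial` with ``circular=True``.
    """
    a = patch.a
    d = patch.pitch
    T = np.fft.fft2(patch.t)
    power = (T * T.conj()).real
    total = float(power.sum())
    if total <= _energy_floor(a, float(np.max(np.abs(patch.t)) ** 2)) * a * a:
        return BandwidthValue(tau=0.0, degenerate=True)
    k = 2.0 * np.pi * np.fft.fftfreq(a, d=d)
    if matched:
        wgt = (np.sin(k * d) / d) ** 2
    else:
        wgt = k**2
    second = float(np.sum((wgt[:, None] + wgt[None, :]) * power))
    return BandwidthValue(tau=float(np.sqrt(second / total)), degenerate=False)


def _gradients(t: np.ndarray, d: float, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    if circular:
        gr = (np.roll(t, -1, axis=0) - np.roll(t, 1, axis=0)) / (2.0 * d)
        gc = (np.roll(t, -1, axis=1) - np.roll(t, 1, axis=1)) / (2.0 * d)
        return gr, gc
    gr, gc = np.gradient(t, d, edge_order=1)
    return gr, gc


def bandwidth_spatial(patch: LocalPatch, circular: bool = False) -> BandwidthValue:
    """Bandwidth τ from gradient energy: τ² = Σ|∇t|² / Σt².

    Central differences with spacing Δ = pitch; ``circular=True`` wraps the
    patch edges (the mode that matches :func:`bandwidth_spectral` with
    ``matched=True`` to machine precision), ``circular=False`` falls back
    to one-sided differences at the patch rim.
    """
    a = patch.a
    energy = patch.energy
    if energy <= _energy_floor(a, float(np.max(np.abs(patch.t)) ** 2)):
        return BandwidthValue(tau=0.0, degenerate=True)
    gr, gc = _gradients(patch.t, patch.pitch, circular)
    grad_energy = float(np.sum(gr * gr + gc * gc))
    return BandwidthValue(tau=float(np.sqrt(grad_energy / energy)), degenerate=False)


def correlation_length(patch: LocalPatch, circular: bool = False) -> float:
    """Local autocorrelation length ρ = 2π √(Σt² / Σ|∇t|²), in μm.

    Returns NaN (flagged invalid, not raised) when the gradient energy is
    below the degeneracy floor — constant or empty windows have no length.
    """
    bw = bandwidth_spatial(patch, circular=circular)
    if bw.degenerate or bw.tau == 0.0:
        return float("nan")
    return 2.0 * np.pi / bw.tau


def _window_sums(arr: np.ndarray, a: int) -> np.ndarray:
    """Sums of every a×a window of ``arr`` via a summed-area table.

    Output[i, j] = arr[i:i+a, j:j+a].sum(); shape (H−a+1, W−a+1).
    Accumulation is double precision regardless of the input dtype.
    """
    padded = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    np.cumsum(arr, axis=0, dtype=np.float64, out=padded[1:, 1:])
    np.cumsum(padded[1:, 1:], axis=1, out=padded[1:, 1:])
    c = padded
    return c[a:, a:] - c[:-a, a:] - c[a:, :-a] + c[:-a, :-a]


def correlation_length_map(phase: PhaseImage, window: WindowSpec | None = None) -> CorrelationLengthMap:
    """Dense ρ map of a phase image by the summed-area-table fast path.

    Steps: (i) central-difference gradient images of ϕ computed once,
    globally, at physical spacing Δ = pitch; (ii) windowed sums of ϕ, ϕ²
    and |∇ϕ|² by summed-area tables; (iii) per center, numerator
    Σt² = Σϕ² − (Σϕ)²/a² (mean-removal identity) and denominator the
    windowed gradient energy.  Centers whose footprint crosses the image
    border, or off the stride grid, or degenerate, are invalid.
    """
    if window is None:
        window = WindowSpec()
    a, stride = window.a, window.stride
    h, w = phase.shape
    if h < a or w < a:
        raise ValueError(f"image {h}×{w} is smaller than the {a}×{a} window")

    phi = phase.values
    d = phase.pitch
    gr, gc = np.gradient(phi, d, edge_order=1)
    grad_sq = gr * gr + gc * gc

    s1 = _window_sums(phi, a)
    s2 = _window_sums(phi * phi, a)
    se = _window_sums(grad_sq, a)

    num = s2 - s1 * s1 / (a * a)  # Σt² per window, rad²
    np.maximum(num, 0.0, out=num)  # clip tiny negative round-off

    floor = _energy_floor(a, float(np.var(phi)))
    ok = (se > floor) & (num > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 2.0 * np.pi * np.sqrt(num / se)
    rho[~ok] = np.nan

    lengths = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    starts_r = np.arange(0, h - a + 1, stride)
    starts_c = np.arange(0, w - a + 1, stride)
    centers_r = starts_r + a // 2
    centers_c = starts_c + a // 2
    lengths[np.ix_(centers_r, centers_c)] = rho[np.ix_(starts_r, starts_c)]
    valid[np.ix_(centers_r, centers_c)] = ok[np.ix_(starts_r, starts_c)]
    lengths[~valid] = np.nan

    return CorrelationLengthMap(
        lengths=lengths, valid=valid, pitch=d, window_pixels=a, name=phase.name
    )
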