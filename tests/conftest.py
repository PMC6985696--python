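"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phasecorr import GaussianFieldSpec, PhaseImage, generate_gaussian_field
from phasecorr.corrlength import WindowSpec


def naive_length_map(phase: PhaseImage, window: WindowSpec) -> np.ndarray:
    """Per-window evaluation of ρ by direct summation — the slow oracle.

    Gradients are full-image central differences (window-as-restriction
    semantics, same as the production path) but every windowed quantity is
    computed by explicit slicing, mean removal and direct sums, with no
    summed-area tables and no algebraic mean-removal identity.  Returns an
    array over window *starts* of shape (H−a+1, W−a+1).
    """
    a = window.a
    phi = phase.values.astype(np.float64)
    d = phase.pitch
    gr, gc = np.gradient(phi, d, edge_order=1)
    e = gr * gr + gc * gc
    h, w = phi.shape
    out = np.full((h - a + 1, w - a + 1), np.nan)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = phi[i : i + a, j : j + a]
            t = block - block.mean()
            num = float(np.sum(t * t))
            den = float(np.sum(e[i : i + a, j : j + a]))
            if den > 0 and num > 0:
                out[i, j] = 2.0 * np.pi * np.sqrt(num / den)
    return out


def random_patch_image(seed: int, n: int = 96, sigma: float = 0.0, pitch: float = 1.0) -> PhaseImage:
    """A seeded random phase image, optionally smoothed to correlation σ px."""
    if sigma > 0:
        f = generate_gaussian_field(GaussianFieldSpec(shape=(n, n), sigma=sigma, std_phase=0.3, seed=seed))
        return PhaseImage(f.values, pitch=pitch)
    rng = np.random.default_rng(seed)
    return PhaseImage(rng.standard_normal((n, n)), pitch=pitch)


@pytest.fixture(scope="session")
def smooth_image_128() -> PhaseImage:
    """128×128 Gaussian-correlated phantom used by fast-vs-naive checks."""
    f = generate_gaussian_field(
        GaussianFieldSpec(shape=(128, 128), sigma=2.0, std_phase=0.4, seed=11)
    )
    return PhaseImage(f.values, pitch=0.25, name="phantom128")
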