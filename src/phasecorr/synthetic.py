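"""Synthetic phase phantoms with known correlation structure.

No quantitative-phase tissue scans are publicly deposited, so the test
bed is a generator of phase images whose ground truth is exact: a
stationary Gaussian-correlated random field — autocorrelation
exp(−r²/(2σ²)), realized by convolving seeded white noise with a Gaussian
kernel of width σ/√2 under wrap-around boundaries and renormalizing to a
target standard deviation — optionally stamped into a disk-shaped
"tissue core" on a near-flat background.  For such a field the spectral
bandwidth is τ = √2/σ in pixel units, so the expected correlation length
is ρ = √2·π·σ·Δ, which parameter-recovery tests lean on.

Every generator output is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .images import DEFAULT_PITCH_UM, PhaseImage

__all__ = [
    "GaussianFieldSpec",
    "CorePhantomSpec",
    "phase_from_index",
    "generate_gaussian_field",
    "generate_core_phantom",
    "generate_cohort",
    "two_class_cohort_specs",
    "four_group_cohort_specs",
]


@dataclass(frozen=True)
class GaussianFieldSpec:
    """Stationary Gaussian-correlated field: autocorrelation exp(−r²/(2σ²))."""

    shape: tuple[int, int] = (512, 512)
    sigma: float = 2.0  # correlation parameter, pixels
    std_phase: float = 0.2  # target standard deviation, rad
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0 pixels, got {self.sigma}")
        if not (self.std_phase > 0):
            raise ValueError(f"std_phase must be > 0 rad, got {self.std_phase}")


@dataclass(frozen=True)
class CorePhantomSpec:
    """A disk-shaped tissue-core phantom on a near-flat background.

    The interior field rides on top of ``background_level`` (no mean step
    at the disk edge); outside the disk only ``background_level`` plus
    small white noise remains, which lands below a ~1.3 μm length
    threshold and thereby exercises the background mask.
    """

    diameter: float = 64.0  # μm
    pitch: float = DEFAULT_PITCH_UM  # μm/pixel
    interior: GaussianFieldSpec = GaussianFieldSpec()
    background_level: float = 0.0  # rad
    background_noise_std: float = 0.01  # rad
    group_label: str = "benign"

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and self.pitch > 0):
            raise ValueError("diameter and pitch must be positive")

    @property
    def npix(self) -> int:
        """Image side length; the disk is inscribed in the square image."""
        return int(round(self.diameter / self.pitch))


def phase_from_index(
    index_contrast: np.ndarray, thickness: float, wavelength: float
) -> PhaseImage:
    """Phase of a z-invariant slab: ϕ = (2π/λ)·n·L per pixel.

    ``index_contrast`` is the (dimensionless) refractive-index contrast
    between tissue and medium, ``thickness`` L and ``wavelength`` λ in μm.
    """
    if not (thickness > 0):
        raise ValueError(f"thickness must be > 0 μm, got {thickness}")
    if not (wavelength > 0):
        raise ValueError(f"wavelength must be > 0 μm, got {wavelength}")
    n = np.asarray(index_contrast, dtype=np.float64)
    return PhaseImage(values=2.0 * np.pi / wavelength * n * thickness, pitch=DEFAULT_PITCH_UM)


def generate_gaussian_field(spec: GaussianFieldSpec) -> PhaseImage:
    """Seeded Gaussian-correlated field, renormalized to the target std.

    White noise is filtered with a Gaussian kernel of width σ/√2
    (wrap-around, so the field is stationary on the torus), then shifted
    and scaled so the sample mean is exactly 0 and the sample standard
    deviation exactly ``std_phase``.
    """
    rows, cols = spec.shape
    if min(rows, cols) < 8 * spec.sigma:
        raise ValueError(
            f"shape {spec.shape} too small for sigma={spec.sigma} px "
            f"(need ≥ {8 * spec.sigma:.0f} per axis)"
        )
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.shape)
    field = ndimage.gaussian_filter(white, sigma=spec.sigma / np.sqrt(2.0), mode="wrap")
    field -= field.mean()
    field *= spec.std_phase / field.std()
    return PhaseImage(values=field, pitch=DEFAULT_PITCH_UM, name=f"gauss_s{spec.sigma}_seed{spec.seed}")


def generate_core_phantom(spec: CorePhantomSpec, seed: int | None = None) -> PhaseImage:
    """One disk-core phantom; ``seed`` overrides the interior spec's seed."""
    seed = spec.interior.seed if seed is None else int(seed)
    n = spec.npix
    interior_spec = replace(spec.interior, shape=(n, n), seed=seed)
    field = generate_gaussian_field(interior_spec).values

    # independent stream for the background noise
    bg_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E37]))
    values = spec.background_level + spec.background_noise_std * bg_rng.standard_normal((n, n))

    c = (n - 1) / 2.0
    rr, cc = np.ogrid[:n, :n]
    disk = (rr - c) ** 2 + (cc - c) ** 2 <= (spec.diameter / (2.0 * spec.pitch)) ** 2
    values[disk] = spec.background_level + field[disk]
    return PhaseImage(
        values=values, pitch=spec.pitch, name=f"{spec.group_label}_seed{seed}"
    )


def generate_cohort(
    specs: list[CorePhantomSpec], seeds: list[int] | np.ndarray
) -> list[tuple[PhaseImage, str]]:
    """Deterministic cohort: one phantom per (spec, seed) pair."""
    if len(specs) != len(seeds):
        raise ValueError(f"{len(specs)} specs but {len(seeds)} seeds")
    return [
        (generate_core_phantom(spec, seed=int(seed)), spec.group_label)
        for spec, seed in zip(specs, seeds)
    ]


def two_class_cohort_specs(
    n_benign: int = 20,
    n_malignant: int = 20,
    sigma_benign: float = 2.0,
    sigma_malignant: float = 1.2,
    diameter: float = 64.0,
    pitch: float = DEFAULT_PITCH_UM,
    std_phase: float = 0.2,
) -> list[CorePhantomSpec]:
    """Benign-like vs malignant-like cores, distinguished only by σ.

    Malignant-like cores use a shorter correlation parameter — the
    disorder-ordering the method is designed to detect.
    """
    mk = lambda sigma, label: CorePhantomSpec(  # noqa: E731
        diameter=diameter,
        pitch=pitch,
        interior=GaussianFieldSpec(sigma=sigma, std_phase=std_phase),
        group_label=label,
    )
    return [mk(sigma_benign, "benign")] * n_benign + [mk(sigma_malignant, "malignant")] * n_malignant


#: Default group sizes mirroring a benign / grade-1 / grade-2 / grade-3 cohort.
FOUR_GROUP_SIZES = {"benign": 20, "grade1": 16, "grade2": 16, "grade3": 14}

#: Default per-group correlation parameters (pixels): monotonically more
#: disordered with grade, endpoints matching the two-class defaults.
FOUR_GROUP_SIGMA = {"benign": 2.0, "grade1": 1.7, "grade2": 1.4, "grade3": 1.2}


def four_group_cohort_specs(
    sizes: dict[str, int] | None = None,
    sigmas: dict[str, float] | None = None,
    diameter: float = 64.0,
    pitch: float = DEFAULT_PITCH_UM,
    std_phase: float = 0.2,
) -> list[CorePhantomSpec]:
    """Benign plus three malignant grades with decreasing σ."""
    sizes = dict(FOUR_GROUP_SIZES) if sizes is None else sizes
    sigmas = dict(FOUR_GROUP_SIGMA) if sigmas is None else sigmas
    specs: list[CorePhantomSpec] = []
    for label, n in sizes.items():
        specs += [
            CorePhantomSpec(
                diameter=diameter,
                pitch=pitch,
                interior=GaussianFieldSpec(sigma=sigmas[label], std_phase=std_phase),
                group_label=label,
            )
        ] * n
    return specs
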