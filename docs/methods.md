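# Methods

## Model and operational definitions

A quantitative phase image ϕ(x, y) of a thin tissue section is treated as
a map of integrated refractive-index contrast: ϕ = (2π/λ)·n·L for a
z-invariant slab of thickness L at illumination wavelength λ. The local
texture statistic computed here is the spatial autocorrelation length ρ
of the mean-removed phase within an a×a sliding window,

    t(x, y; x′, y′) = ϕ·w − ⟨ϕ·w⟩,        Γ = t ⊗ t,

defined operationally through the spectral bandwidth τ — the root second
moment of the window's power spectrum — and the product law ρ·τ = 2π.
With Parseval's theorem and the differentiation property of the Fourier
transform the bandwidth becomes a ratio of two spatial sums,

    τ² = Σ(|∂t/∂x|² + |∂t/∂y|²) / Σ|t|²,
    ρ  = 2π √( Σ|t|² / Σ(|∂t/∂x|² + |∂t/∂y|²) ),

so no per-window transform is ever taken.

A direct "variance of the normalized autocorrelation" definition of ρ²
(second moment of Γ divided by ∬Γ) is sometimes written down for this
quantity, but it is ill-posed for mean-removed windows: ∬Γ equals
|T(0)|², which is identically zero when t has zero mean. This package
therefore documents that form but never computes it; ρ·τ = 2π *is* the
definition, and the `Autocorrelogram` type exists as an inspectable
intermediate, not as the computational route.

## The fast map

For every window position the numerator and denominator factorize into
windowed sums of three globally precomputed images:

1. gradient images of ϕ, computed **once** by central differences at
   physical spacing Δ = pitch (`numpy.gradient`, one-sided at the image
   border), giving the gradient-energy image |∇ϕ|²;
2. summed-area tables of ϕ, ϕ², and |∇ϕ|², giving every a×a window sum
   in O(1);
3. per center, Σt² = Σϕ² − (Σϕ)²/a² (the subtracted window mean has zero
   gradient, so mean removal touches only the numerator — an exact
   algebraic identity, not an approximation).

The window acts as a *restriction*: gradients are evaluated on the full
image, so window-rim pixels carry true central differences and the
artificial edge of the excerpt contributes no spurious gradient energy.
Accumulation is double precision throughout; single-precision
summed-area tables lose digits already at megapixel scale. The whole
dense map is one pass over the image, independent of window size.

Conventions: (row, column) indexing, 0-based, pixel centers at integer
coordinates; for even a the footprint of center r spans rows
r − a/2 … r + a/2 − 1. Centers whose footprint crosses the border, or
that fall off the stride grid, are invalid. A window whose gradient
energy falls below `1e-12 · a² · max(1, var(ϕ))` is degenerate —
flagged invalid, never clamped to a substitute length. Invalid pixels
are stored as NaN in the float32 output TIFF, with pitch and window
width carried in the description tag.

## Defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| window width a | 64 | px | 8 μm at the default pitch: large enough for a stable spectral second moment, small enough to stay local to one gland/stroma neighbourhood |
| pitch Δ | 0.125 | μm/px | an 880 μm tissue core spanning 7040 px; always overridable |
| stride | 1 | px | dense map; raise for speed, values on the coarse grid are identical to the dense ones |
| background threshold | 1.3 | μm | mounting medium / empty substrate resolves as very short ρ; strict `<` removes it, equality survives |
| feature | mean(ρ)/std(ρ) | — | per core over all foreground pixels pooled; sample (n−1) standard deviation, fixed for testability (immaterial at map-scale n) |
| rank-sum switch | n ≤ 12, tie-free | — | exact enumeration where cheap; asymptotic with tie and continuity corrections at realistic group sizes |

## Discrete-operator choices and their bias

The derivative operator is nowhere canonical; central differences were
chosen for symmetry and for their clean transfer function i·sin(kΔ)/Δ,
which gives the frequency-domain twin (`bandwidth_spectral` with
`matched=True`) that equals the circular spatial route to machine
precision — the dual-route identity the test battery leans on.

Central differences under-measure gradient energy at high spatial
frequency: for a field whose per-axis spectral variance is s² = 1/σ²
(σ the Gaussian correlation parameter in pixels), the measured bandwidth
satisfies τ̂²/τ² = (1 − e^{−2s²})/(2s²), so ρ is overestimated by
×1.23 at σ = 1.5 px, ×1.13 at σ = 2, ×1.06 at σ = 3, vanishing for
smooth fields. Two consequences worth knowing:

* parameter-recovery accuracy against the continuum form ρ = √2·π·σ·Δ is
  ~5% at σ = 3 px but degrades to ~20%+ for σ < 2 px; recovery tests at
  those σ document the measured ratios rather than passing a 10% band;
* conversely the operator is exactly calibrated in the white-noise
  limit, where E[τ̂²] = 1/Δ² and the map mean reproduces ρ = 2πΔ to a
  fraction of a percent.

No alternative operator fixes both regimes at once: a first-order
difference roughly halves the smooth-field bias but breaks the
white-noise calibration by a factor of 2, and a spectrally exact
derivative makes τ̂ diverge toward the Nyquist-weighted moment on noisy
data. Central differences are the documented compromise.

## Synthetic phantoms

`generate_gaussian_field` filters seeded white noise with a Gaussian
kernel of width σ/√2 under wrap-around boundaries (hence exactly
stationary) and renormalizes affinely, so the field has sample mean 0,
sample std exactly `std_phase`, and autocorrelation exp(−r²/(2σ²)) with
spectral bandwidth τ = √2/σ px⁻¹ — every recovery test has a closed-form
target. `generate_core_phantom` stamps such a field into a disk
("tissue core") inscribed in the image; outside remains the background
level plus 0.01 rad white noise, which the length map resolves as
ρ ≈ 2πΔ ≈ 0.8 μm at the default pitch, i.e. below the 1.3 μm mask — the
background-removal behaviour seen on real substrate. The interior field
rides on the same base level (no mean step at the disk edge), so edge
windows mix variances but see no artificial step texture. The disk edge
is hard; feathering would only soften a transition the mask already
handles. Default cohort effect sizes (benign-like σ = 2.0 px down to
malignant-like σ = 1.2 px, sizes 20/16/16/14 for the four-group design)
are generator conventions for exercising the pipeline, not claims about
tissue.

What the phantoms deliberately do **not** emulate: interferometric image
formation (halo, partial coherence, defocus), fixation/section-thickness
variability, or any anatomical structure. Passing recovery and cohort
tests therefore demonstrates correctness of the *computation* on fields
with known truth, not diagnostic performance on tissue.

One interaction deserves emphasis: at the default 0.125 μm/px pitch,
interior correlation lengths for σ ≤ ~2.3 px fall *below* the 1.3 μm
background threshold (benign-like σ = 2.0 px ⇒ ρ̂ ≈ 1.24 μm, malignant-
like σ = 1.2 px ⇒ ρ̂ ≈ 0.90 μm), so the default mask classifies such
interiors as background and the foreground mean/std feature becomes
undefined for the malignant-like group. Group separation on these
phantoms is demonstrated on per-core mean ρ over valid pixels, or with a
threshold suited to the phantom geometry (see
`examples/cohort_comparison.py`); on real tissue, where ρ runs well
above 1.3 μm, the default mask behaves as intended.

## Degenerate inputs and tie-breaks

Constant images (and constant windows) are flagged invalid rather than
given a length; a map with zero valid centers is legal output. Feature
extraction requires ≥ 2 foreground pixels and nonzero dispersion, and
raises otherwise — at cohort level such cores are recorded as row
failures and skipped, with a nonzero exit code. Rank-sum p-values are
capped at 1; identical groups return exactly 1. The comparison table
emits a fixed eight-row layout (benign vs pooled malignant, low-risk vs
high-risk pooling, all six pairwise rows) when the four canonical groups
are present, otherwise all pairwise rows in sorted order.

## Problem sizes

The test battery and `scripts/acceptance.py` run the exact identities on
100 random 64×64 patches, fast-vs-naive equivalence on a 128² phantom
(4225 windows), recovery statistics on 256² fields (≈2k–31k interior
centers), and the cohort analogue on forty 512² disk phantoms — sizes
chosen so every quantity is statistically stable while the whole battery
completes in well under a minute on one CPU; the map itself scales
linearly and handles the 7040² full-core geometry unchanged.
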