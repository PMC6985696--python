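# phasecorr

Local spatial autocorrelation length maps from quantitative phase images
of tissue, and the per-core statistics that make them usable as a
label-free grading marker.

## The problem and the method

Quantitative phase imaging (QPI) measures, per pixel, the optical
path-length delay ϕ(x, y) = (2π/λ)·∫ n dz through a thin specimen — for a
tissue section of near-constant thickness, a map of integrated
refractive-index contrast. Carcinogenesis disorders tissue refractive
index at the nanoscale, which *shortens* the distance over which phase
fluctuations stay spatially correlated. That length is the quantity this
package maps.

Within a small window of width *a* centered at (x′, y′), form the
mean-removed phase t = ϕ·w − ⟨ϕ·w⟩. Its autocorrelation Γ = t ⊗ t has a
width ρ(x′, y′), related to the root second moment τ of the window's
spatial power spectrum by ρ·τ = 2π. By the differentiation property of
the Fourier transform and Parseval's theorem, τ needs no transforms at
all:

    τ² = Σ |∇t|² / Σ |t|²,      ρ = 2π · sqrt( Σ|t|² / Σ|∇t|² ).

Because the gradient of the subtracted window mean vanishes and
Σt² = Σϕ² − (Σϕ)²/a², a *dense* ρ map over every window position reduces
to three global images (ϕ, ϕ², |∇ϕ|²) plus O(1) sliding-window sums via
summed-area tables — no per-window FFTs, one pass over the image
regardless of window size. Downstream, background pixels (ρ below a
threshold, default 1.3 μm) are masked out, each tissue core is summarised
by the dimensionless feature mean(ρ)/std(ρ) over its foreground, and
diagnostic groups are compared with two-sided Wilcoxon rank-sum tests.

Since no QPI tissue scans are publicly deposited, the package ships a
synthetic module generating phase phantoms with exactly known correlation
structure (Gaussian autocorrelation exp(−r²/(2σ²)), for which
ρ = √2·π·σ·Δ in the continuum limit), used by the entire test battery.

## Worked example

```sh
$ python examples/length_map_basics.py
valid interior centers : 1936
mean interior rho      : 14.025 um
continuum expectation  : 13.329 um  (sqrt(2)*pi*sigma*pitch)
ratio measured/expected: 1.0523
```

A σ = 3 px Gaussian-correlated field at 1 μm/px should have
ρ = √2·π·3 ≈ 13.33 μm; the map recovers 14.03 μm. The ~5% excess is the
known discretization bias of central differences on coarsely sampled
fields (quantified in `docs/methods.md`), shrinking as σ grows.

```sh
$ python examples/cohort_comparison.py
benign_seed5           n_fg=  4225  mean=1.237 um  std=0.028 um  feature=43.70
...
malignant_seed20       n_fg=  4225  mean=0.908 um  std=0.009 um  feature=102.67

rank-sum W = 36.0, two-sided p = 0.000939
```

Eight benign-like (σ = 2.0 px) versus eight malignant-like (σ = 1.2 px)
disk phantoms: the malignant-like cores have visibly shorter mean ρ
(0.90 vs 1.24 μm) and the mean/std feature separates the groups at
p ≈ 9×10⁻⁴.

`examples/bandwidth_identities.py` shows the two τ routes (gradient
energy vs matched spectral second moment) agreeing to machine precision
and the exact product law ρ·τ = 2π.

The same pipeline is scriptable from the shell:

```sh
phasecorr phantom cohort/ --seed 7        # disk phantoms + manifest.csv
phasecorr map cohort/benign_000.tif -o rho.tif --window 64
phasecorr mask rho.tif -o rho_masked.tif --threshold 1.3
phasecorr cohort cohort/manifest.csv -o stats/
```

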