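# Methods

## The mixture model

A simulated 1D ¹H spectrum is the weighted sum of pure-compound reference
spectra, `y(δ) = Σₖ cₖ pₖ γₖ(δ)`, over the metabolites of the panel.
The package stores each reference spectrum normalized so that its
trapezoidal integral equals the compound's observable proton count `pₖ`
(one area unit per proton at unit concentration). This makes the proton
weighting part of the stored spectrum: simulation reduces to multiplying
each normalized spectrum by its concentration `cₖ` (μM) and summing, and
the summation is exactly linear — superposition and homogeneity hold to
floating-point precision, which the test suite asserts at 1e-12 relative.

Assumptions inherited from the linear-combination model: resonance
positions and lineshapes do not depend on the mixture composition (no
intermolecular interaction, no strong-coupling changes between pure
compound and mixture), and detector response is linear in concentration.
pH is the only effect that moves peaks, and it is modeled explicitly.

Spectra live on a uniform chemical-shift grid stored in descending ppm
(display convention). The default common grid spans 9.995 → −0.005 ppm
with 2¹⁵ points (≈ 0.000305 ppm/pt, the resolution of a typical processed
1D acquisition); tests and the acceptance script use 4096-point grids,
which keeps the suite fast while leaving peaks (FWHM ≈ 0.0025 ppm at
1.5 Hz / 600 MHz, broadened to the grid floor, see below) resolvable.
A residual-water window, 4.5–5.0 ppm by default, is zeroed before
normalization — both in the loader and in the fixture generator, so that
writing and re-loading a library is exact.

## Concentration designs

**Case–control.** Literature concentration entries are either (mean, SD)
pairs or [min, max] ranges; ranges are interpreted as 99.7% (3σ) normal
intervals, i.e. mean = midpoint and SD = span/6. Multiple entries for one
metabolite/condition are pooled by unweighted arithmetic means of both
the means and the SDs. Group-specific statistics come either from
per-condition library metadata or from fold change × mean and
SD ratio × SD applied to the baseline ("normal") group. Concentrations
are drawn from a normal truncated at zero (scipy's `truncnorm`, i.e.
conditioning, not clipping), so marginals are exact.

**Continuous response.** The response `y` (age, BMI, …) is drawn
`N(μ_y, σ_y²)` for n replicates; each metabolite's standardized
concentration is `z_x = a·z_y + ε`, `ε ~ N(0, eps_sd²)`, where `z_y`
standardizes the drawn responses by their *sample* mean and SD. Writing
the regression of x on y this way realizes `corr(x, y) = a` exactly in
population when `eps_sd = √(1−a²)`; if the user sets a different
`eps_sd`, the realized correlation `a/√(a² + eps_sd²)` is reported in the
log. With `a = 0` and `eps_sd = 0` (the defaults) the metabolite is held
constant at its mean. Concentrations are mapped back to the raw scale by
`x = x̄ + σ_x·z_x` and clipped at zero; at the μM means and SDs typical of
biofluid panels (mean/SD ≥ 3) the clip is inactive for essentially all
draws. n < 3 is rejected because sample-SD standardization is undefined.

**Inter-metabolite correlation.** A Gaussian copula: draw multivariate
normal with the target correlation matrix R, scale each marginal to its
(mean, SD), clip at zero. R is validated (symmetric, unit diagonal,
entries in [−1,1]); a non-positive-semi-definite R is repaired by
eigenvalue clipping at 1e-8 and rescaling to unit diagonal, with a
logged warning — an already-PSD matrix is returned unchanged. Clipping at
zero slightly attenuates extreme correlations; at mean/SD ≥ 3 the
distortion is below Monte-Carlo noise at n = 10⁴ (tested at ±0.05).

## pH-dependent peak shifting

Peak clusters are detected on the pure-compound spectrum by a
two-threshold run scan: clusters are maximal runs of points at or above
`cluster_threshold_frac × max`, and a cluster survives only if it
contains an apex — a local maximum at or above `main_threshold_frac ×
max`. Apexes use a ≥-left / >-right neighbor rule (plateaus yield their
rightmost point), which makes the detector exactly reproducible against a
brute-force oracle. Defaults: main 0.10, cluster 0.02 of the global max.

Each cluster moves by the Henderson–Hasselbalch shift

    Δδ = (δ_L − δ_HL) · (σ(pH₀−pKa) − σ(pH₁−pKa)),   σ(t) = 10ᵗ/(1+10ᵗ),

between the acid-limit position δ_L and basic-limit position δ_HL. The
two-logistic form is algebraically identical to the ratio form
`(10^(pH₀−pKa) − 10^(pH₁−pKa)) / ((1+10^(pH₀−pKa))(1+10^(pH₁−pKa)))` but
cannot overflow at any |pH−pKa|; it makes the invariants transparent:
Δδ = 0 at pH₁ = pH₀, |Δδ| ≤ |δ_L−δ_HL|, antisymmetry under swapping the
two pH values, and monotone decrease in pH₁ when δ_L > δ_HL. The
reference pH₀ defaults to the physiological 7.4.

Limit pairs are matched to detected clusters in ppm order; clusters
beyond the stated list are imputed (if imputation is enabled, the
default) or left in place. A missing pKa is imputed from
`N(7.0, 2.0²)` clamped to [0, 14], and a missing limit span from
`N(0.05, 0.02²)` ppm — defaults chosen to cover the range of reported
urinary-metabolite pH sensitivities; both are configurable and every
imputation is driven by the run's seeded substream.

Shifts are quantized to whole grid points (round to nearest). At the
default grid this quantization error (≤ 0.00015 ppm) is an order of
magnitude below the linewidth, and it buys exact integral conservation
and exact commutation between shifting and 2D projection, both asserted
in the tests. Each simulated replicate draws one sample pH from
`N(pH_mean, pH_sd²)` shared by all metabolites in that spectrum; each
metabolite is shifted with its own pKa and limits before summation.
Clusters relocated onto the same grid points are summed during cohort
simulation (superposition of real resonances); the low-level shift
operations default to raising instead, for use as validated primitives.

## 2D spectra

J-Res grids put multiplet structure on F1 (Hz) and chemical shift on F2
(ppm); COSY grids are square and symmetric in ppm. Mixtures are the same
weighted sums; every record's 2D grid carries the same total intensity
budget as its 1D spectrum (summing a J-Res grid over F1 gives a profile
whose F2 integral equals the proton count), so 2D weights are consistent
with 1D ones. Shifting detects clusters on the skyline projection
(columnwise max, J-Res) or diagonal trace (COSY) and relocates F2 column
blocks; COSY blocks are relocated along both axes, which preserves
symmetry and moves cross peaks together with their diagonal blocks —
cross peaks do not get independent pH sensitivities (limitation).

## Synthetic fixtures

The generator emulates processed pure-compound spectra with Lorentzian
multiplets: first-order patterns s/d/t/q at offsets 0, ±J/2, {−J, 0, +J},
{±J/2, ±3J/2} with Pascal-ratio amplitudes (1 | 1:1 | 1:2:1 | 1:3:3:1),
J of 3–12 Hz, linewidths 1–2 Hz FWHM, at a default spectrometer frequency
of 600 MHz (1 Hz = 1/600 ppm). Random libraries draw peak centers
uniformly on 0.8–9.0 ppm avoiding the water window; at least half the
records carry pKa and per-multiplet shift limits so the pH path is
exercised, and every record carries "normal" plus one abnormal
condition's statistics (means 50–500 μM, SD = mean/10, fold changes
0.5–2). Blood libraries add a protein background: a smooth sum of broad
Gaussians (σ 0.15–0.5 ppm near 0.9, 1.3, 2.0, 3.0 and 7.3 ppm)
normalized to a stated total area, emulating the albumin envelope.

2D fixture grids live on their own, coarser F2 axis (1024 points by
default) — 2D acquisitions have far fewer points per dimension than 1D
ones, and a full-resolution square COSY matrix would be prohibitively
large. On coarse grids a 1.5 Hz Lorentzian falls between samples, so 2D
line widths are floored at two grid steps and each sampled line is
rescaled to its exact analytic area.

What the fixtures do **not** reproduce: second-order (strong-coupling)
multiplet distortions, lineshape changes with pH or ionic strength,
baseline artifacts, lipoprotein macromolecule profiles, and the true
spectral crowding of a real biofluid. Passing tests therefore demonstrate
the correctness of the simulation machinery — linearity, shift algebra,
design recovery, determinism — not field realism of any particular
library; realism is inherited from whatever experimental reference
library the user loads.

## Noise and seeds

Noise is additive white Gaussian with SD expressed as a fraction of the
clean spectrum's maximum (same convention in 2D); the default is 0 — no
noise unless requested — and the clean maximum is recorded in provenance.
One master seed drives named substreams (concentrations, pH,
per-replicate noise, per-replicate pKa imputation) derived via
`SeedSequence(master, spawn_key=...)`, so toggling noise does not perturb
concentration draws, and every cohort is bit-identically reproducible
from its manifest. Group declaration order is part of the reproducibility
contract (groups are simulated in order), so manifests preserve key
order.

## Problem sizes

The test suite and acceptance script use 4096-point 1D grids, 512-point
2D axes, cohorts of up to 100 replicates × 50 seed repetitions
(continuous recovery) and 1000 per group (fold-change recovery), and
Monte-Carlo checks at n = 10⁴–10⁵. These sizes put Monte-Carlo error
comfortably inside the asserted tolerances (e.g. SE of a mean correlation
over 50 × n=100 repetitions ≈ 0.003 against a ±0.05 band) while the whole
suite runs in well under a minute.

## Known limitations

- No quantum-mechanical spin simulation: multiplets are first-order
  Lorentzian sums; rooftop effects and higher-order patterns are absent.
- COSY cross peaks shift with their diagonal blocks, not with the pH
  sensitivities of both coupled protons.
- Lineshape is pH-invariant; only positions move.
- No lipoprotein/macromolecule lineshape model beyond the smooth protein
  envelope; no FID-domain effects (apodization, phasing artifacts).
- The on-disk library format is plain TSV; vendor-format readers are out
  of scope.
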