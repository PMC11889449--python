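# metabomix

Simulation of realistic 1D and 2D (J-resolved and COSY) ¹H NMR spectra of
biofluid metabolite mixtures — urine, blood and cerebrospinal fluid — with
labeled cohort designs for benchmarking annotation, quantification and
machine-learning methods.

Experimental NMR datasets with ground-truth labels are scarce, which limits
the development of statistical and deep-learning methods for metabolomics.
`metabomix` generates arbitrarily large labeled cohorts of mixture spectra
whose generating concentrations, sample pH values and peak shifts are all
recorded, so every simulated spectrum comes with its complete ground truth.

## Model

A mixture spectrum is a linear combination of pure-compound reference
spectra:

```
y(δ) = Σₖ cₖ pₖ γₖ(δ)
```

where `y(δ)` is the mixture intensity at chemical shift `δ` (ppm), `cₖ` the
concentration of metabolite `k`, `pₖ` its observable proton count and
`γₖ(δ)` its reference spectrum. The library normalizes each `γₖ` to one
area unit per proton at unit concentration, so `pₖ` is folded into the
stored spectrum and simulation is a plain weighted sum.

Around this core:

- **Concentrations.** Case–control designs draw each metabolite from a
  truncated normal (≥ 0) with per-group (mean, SD), obtained directly or by
  fold change / SD ratio against the baseline group; literature ranges
  `[min, max]` are read as 3σ intervals (mean = midpoint, SD = span/6).
  Continuous designs generate a response `y` (e.g. BMI) and standardized
  concentrations `z_x = a·z_y + ε`, realizing Pearson correlation `a`
  exactly when `SD(ε) = √(1−a²)`. A Gaussian copula imposes
  inter-metabolite correlation.
- **pH shifts.** Peak clusters detected by a two-threshold run scan move
  between their acid/basic limit positions `δ_L, δ_HL` according to the
  Henderson–Hasselbalch protonation equilibrium,
  `Δδ = (δ_L − δ_HL)·(σ(pH₀−pKa) − σ(pH₁−pKa))` with
  `σ(t) = 10ᵗ/(1+10ᵗ)`; missing pKa values and limit spans are imputed
  from configurable normal distributions.
- **2D modes.** J-Res grids (F1 in Hz carrying multiplet structure, F2 in
  ppm) and symmetric COSY grids are summed with the same weights; shifting
  operates on skyline (J-Res) or diagonal (COSY) projections and relocates
  whole F2 column blocks, moving COSY blocks along both axes to preserve
  symmetry.
- **Blood.** A broad albumin-like envelope is added with a configurable
  scale to emulate the serum protein background.

A synthetic fixture generator (Lorentzian multiplets with Pascal-ratio
line intensities, separable 2D peaks, Gaussian protein envelope) makes the
whole pipeline runnable and testable with no experimental data.

## Worked example

Simulate 100 blood-like replicates in which one metabolite tracks a
continuous response with designed correlation a = 0.8:

```python
import numpy as np
from metabomix import (
    ContinuousDesign, MetaboliteResponse, MixtureSpec,
    make_ppm_axis, make_toy_library, simulate_cohort,
)

axis = make_ppm_axis(n_points=4096)
library = make_toy_library(5, seed=42, axis=axis, with_2d=False)
a = 0.8
design = ContinuousDesign(
    n=100, response_mean=25.0, response_sd=4.0,
    metabolites={
        mid: MetaboliteResponse(
            200.0, 20.0,
            a=a if mid == "tm000" else 0.0,
            eps_sd=np.sqrt(1 - a**2) if mid == "tm000" else 1.0,
        )
        for mid in library.ids()
    },
)
cohort = simulate_cohort(library, design, MixtureSpec(seed=7))

apex = axis[np.argmax(library["tm000"].spectrum_1d.intensity)]
sel = np.abs(axis - apex) <= 0.2
mat = cohort.to_matrix()
integrals = np.trapezoid(mat[:, sel][:, ::-1], axis[sel][::-1], axis=1)
r = np.corrcoef(integrals, cohort.table.labels)[0, 1]
print(f"tm000 peak region: {apex:.3f} ppm")
print(f"designed correlation a = {a}")
print(f"recovered correlation r = {r:.3f}")
```

prints

```
tm000 peak region: 7.841 ppm
designed correlation a = 0.8
recovered correlation r = 0.789
```

i.e. integrating the simulated spectra over the metabolite's peak region
recovers the designed metabolite–response correlation (0.789 vs 0.8; the
residual gap is finite-sample noise at n = 100). `cohort.table` holds the
generating concentrations and response values — the supervised labels.

## Command line

```
metabomix make-fixtures --n-metabolites 5 --seed 1 --out lib/
metabomix simulate-1d   --config run.yaml --out out/     # also: simulate-jres, simulate-cosy
```

The YAML config format is documented in `metabomix/config.py`; each run
writes per-replicate spectra (TSV), the label table, a provenance sidecar
and a manifest whose replay reproduces all outputs bit-identically.

Reference libraries on disk are a directory with `library.tsv` (id, name,
protons, pKa, per-condition concentration stats, acid/basic shift limits)
plus one 2-column TSV spectrum per record and optional dense-matrix 2D
grids; `write_library`/`load_library` round-trip this format.

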