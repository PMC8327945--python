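# karyoscale

Multi-scale analysis of how the nucleus-to-cell volume ratio (the
karyoplasmic or **N:C ratio**) scales with cell size — for comparative and
cell biologists asking whether larger cells have proportionally larger
nuclei, or relatively smaller ones.

## The model

Everything revolves around the allometric power law

```
nucleus_volume = a · cell_volume^b
```

with normalization constant *a* and size-scaling exponent *b*, fitted on
log10–log10 axes. Regressing the N:C ratio directly on cell volume is
statistically treacherous (cell volume sits on both sides of the model),
so trends in the ratio are read from the algebraic rearrangement

```
log10(N/C) = log10(a) + (b − 1) · log10(C)
```

whose slope is exactly **b − 1**: if the 95% interval of b − 1 contains 0
the ratio is size-invariant (isometry); b < 1 (hypoallometry) means larger
cells have relatively smaller nuclei. The package estimates b at three
biological scales:

* **within species** — OLS on log-transformed cell tables (major-axis and
  quantile regression as robustness checks), with the field's inclusion
  rules: at least 20 observations per dataset, experimentally manipulated
  strains excluded;
* **among species** — a calibration ANCOVA converting DNA content (pg,
  the C-value) to nucleus volume with one shared slope and clade-specific
  intercepts, then a from-scratch Bayesian phylogenetic mixed model
  ("animal model") with a clade fixed effect, a phylogenetic random effect
  proportional to shared branch length, clade-specific residual variances,
  inverse-Wishart priors and a Gibbs sampler, including the
  interaction-drop model-simplification rule and Geweke convergence
  diagnostics;
* **among artificially size-selected lineages** — a REML linear mixed
  model with a generation blocking factor and correlated random
  slope + intercept per lineage nested within generation.

A synthetic-data module generates all three kinds of input with known
ground truth (Yule trees, Brownian-motion traits, power-law cell tables,
a three-treatment selection design), so every estimator is testable for
parameter recovery.

## Worked example

```python
from karyoscale import (
    simulate_within_species, fit_allometry, nc_ratio_slope,
    classify_isometry, fold_change_per_decade,
)

cells = simulate_within_species(b=0.58, log10_a=-0.6, n=1000, seed=42)
fit = fit_allometry(cells["cell_volume_um3"], cells["nucleus_volume_um3"])
print(fit.b, fit.b_ci)            # 0.579 (0.569, 0.589)
print(nc_ratio_slope(fit))        # (-0.421, (-0.431, -0.411))
print(classify_isometry(fit))     # hypoallometric
print(fold_change_per_decade(fit))  # 3.79
```

The fitted exponent b ≈ 0.58 recovers the planted value; the N:C slope
b − 1 ≈ −0.42 with a CI excluding 0 says the ratio falls measurably with
cell size, and 10-fold larger cells carry only ~3.8-fold larger nuclei.

The scripts in `examples/` walk through each capability (unit conversion,
within-species fits, DNA calibration, the phylogenetic model, the
selection experiment, the full pipeline); each prints the numbers it
computes with a line on what they mean. The `karyoscale` command exposes
the same steps from a shell (`karyoscale --help`).

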