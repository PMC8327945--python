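# Methods

This note documents the statistical models implemented in `karyoscale`,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## The allometric core and the b − 1 rearrangement

All analyses model nucleus volume N (μm³) against cell volume C (μm³) as
a power law N = a·C^b and fit it linearly on log10–log10 axes. The N:C
ratio is never regressed on cell volume directly: because C is the
denominator of the response, such a regression is spurious by
construction. Instead the fitted model is rearranged *after* estimation,
log10(N/C) = log10 a + (b − 1)·log10 C, so the ratio's trend is the
derived slope b − 1 with the same confidence interval shifted by −1. The
two decision rules — "1 ∈ CI(b)" and "0 ∈ CI(b − 1)" — are equivalent by
construction, and the package tests that equivalence to machine
precision (log(N/C) = log N − log C makes it exact algebra).

Decision boundaries are inclusive: a CI endpoint exactly at 1 (or 0 in
rearranged form) classifies as isometric. One upstream description of the
decision rule states "b − 1 greater than 1" for hyperallometry while
simultaneously defining isometry as "0 in the CI of b − 1"; these cannot
both be meant, and this package implements the 0-threshold reading
(b − 1 > 0 ⇒ N:C rises, b − 1 < 0 ⇒ N:C falls), which is the only one
consistent with the isometry rule.

### Line-fitting methods

* **OLS** (default, and the recommended estimator for allometry in
  evolutionary biology): t-based CI with n − 2 degrees of freedom,
  two-sided 95%.
* **Major axis**: slope from the first principal axis of the log–log
  scatter. The CI inverts Jolicoeur's rotation test — for a hypothesised
  slope, rotating the data to that axis makes the rotated coordinates
  uncorrelated under H0, tested with t = r√((n−2)/(1−r²)); the CI is the
  set of slopes not rejected, found by bracketed root-finding on the
  angle. If no angle on a side is rejected the bound is reported as
  infinite. MA is appropriate when both axes carry comparable error; its
  median is unbiased at b = 1 under symmetric errors (property-tested).
* **Quantile regression** (default τ = 0.5): statsmodels `QuantReg` with
  its asymptotic kernel-based CI, recorded in the fit metadata.

`fold_change_per_decade` reports 10^b, the multiplicative change in
nucleus volume per 10-fold change in cell volume (10 under isometry).

## Data model and hygiene rules

Species trait tables and cell tables are pandas DataFrames with fixed
units (μm³, pg) declared in the column names. Invariants enforced at
validation: strictly positive volumes, nucleus < cell for every cell
(containment), at least one of nucleus volume / DNA content per species,
and clade labels from a declared vocabulary. The default vocabulary holds
nine clades — bacteria, phytoplankton, angiosperms, fish, frogs,
salamanders, reptiles, birds, mammals — with Amphibia pre-split into
frogs and salamanders because the two occupy non-overlapping cell-size
ranges; the vocabulary is user-extensible, and clade assignment is user
input, never auto-detected.

Hygiene rules applied before within-species fits:

* **Per-species averaging**: repeated measurements collapse to the
  arithmetic mean of raw (linear-scale) values — the plain reading of
  "the average"; log-scale averaging was the alternative and is not used.
  The operation is idempotent, and conflicting clade labels for one
  species are an error.
* **Minimum observations**: datasets with fewer than 20 usable rows are
  excluded (boundary inclusive). Manipulated rows are removed *first*, so
  the threshold counts rows that would actually be analysed.
* **Manipulated-strain exclusion**: rows flagged as experimentally
  manipulated (e.g. N:C-ratio mutants) are dropped by default.

Unit conversions (`geometry`): V = (4/3)π(√(A/π))³ from cross-sectional
area, (4/3)π(D/2)³ from diameter, and (4/3)π(L/2)(W/2)² for a prolate
spheroid from length × width. Width > length raises rather than swapping
silently — swapped inputs usually mean transposed columns upstream. No
other shape models are offered. Which conversion applies to which dataset
is a per-dataset configuration choice.

Newick trees are parsed and written through dendropy; trees are treated
as rooted, tip names must be unique, branch lengths must be nonnegative,
and a missing branch length defaults to 1.0 with a logged warning (tree
compilations do not always guarantee lengths).

## DNA → nucleus-volume calibration

Genome size (C-value, pg) is reported far more often than nucleus volume
and the two are close to proportional. The calibration is an ordinary
ANCOVA on log10 axes — no phylogenetic correction at this step:

    log10 N = intercept(clade) + slope · log10 DNA + ε

Slope homogeneity across clades is checked with a partial F-test on the
clade × DNA interaction at α = 0.05 (the simplification criterion used in
the Bayesian models is a credible interval; for this standalone ANCOVA a
frequentist test is the natural analogue). If the interaction is
significant, the shared-slope model is still returned with
`homogeneous_slopes = False` and per-clade slopes logged — the caller
decides what to do. Improvements at floating-point rounding scale are not
treated as evidence of heterogeneity. Clades with fewer than 3 usable
species are excluded (their intercepts would be noise), not pooled.

Predictions back-transform 10^(intercept + slope·log10 DNA); on the
natural scale these are *medians* (no log-normal bias correction), with
t-based 95% prediction intervals computed on the log10 scale (residual
variance plus the mean-estimation variance at the new x, with the
intercept/slope covariance neglected) and back-transformed. Augmentation
fills only rows lacking a measured nucleus; measured values are never
overwritten, and downstream models use the point predictions (intervals
are exposed for sensitivity analysis).

## Phylogenetic mixed model

Among-species data violate independence: related species resemble each
other. The model, on log10 scales, is

    y = Xβ + u + e,  u ~ N(0, σ²_p·Ã),  e_i ~ N(0, σ²_clade(i))

with y log10 nucleus volume, X an intercept, log10 cell volume, clade
main effects and optionally the clade × cell-volume interaction; u the
phylogenetic random effect with à the species × species matrix of shared
root-to-MRCA branch lengths, scaled by its maximum diagonal so σ²_p is
unit-comparable across trees (an invertible, documented choice); and
clade-specific residual variances (diagonal heterogeneous structure — the
implementation of "clade as a residual covariance structure"). Clade
intercepts are fixed effects. A 1e-10 diagonal jitter stabilises the
Cholesky factorisation; Ã must pass an eigenvalue floor of −1e-8.

Priors: β ~ N(0, 10⁸·I); every variance component gets the scalar
inverse-Wishart (= inverse-gamma) prior with scale V = 1 and degree of
belief ν = 0.002, the conventional weakly-informative choice for this
model family; both hyperparameters are configurable. All full
conditionals are conjugate, so the sampler is pure Gibbs — a joint
multivariate-normal draw for β, a joint draw for u, inverse-gamma draws
for σ²_p and each σ²_clade — with no tuning, no adaptation, and exact
detailed balance. Random numbers are consumed in a fixed per-iteration
order, so extending a chain leaves its earlier retained samples
bit-identical (tested).

Chain settings default to nitt = 500,000, thin = 100, burn-in = 10,000 —
retaining ⌊(nitt − burnin)/thin⌋ = 4,900 samples per chain — with ≥ 2
chains seeded deterministically from one master seed. Variance components
can be pinned (`fixed_variances`) for oracle testing: with known
variances the posterior mean of β must equal the closed-form GLS
estimate, which the acceptance suite checks on a 12-species tree.

**Model simplification**: if every interaction coefficient's 95% credible
interval spans 0, the model is refitted with main effects only and the
summary reports a common slope with clade intercepts and
`interaction_dropped = True`; otherwise clade-specific slopes stand. With
genuinely clade-varying exponents (0.6 vs 0.9 at low noise) the
interaction is retained in ≥ 90% of replicates (tested).

**Convergence**: Geweke z-scores per parameter compare the first 10% of
each retained chain with the last 50%, standardised by AR-spectrum
estimates of each segment's long-run variance (order chosen by AIC via
Yule-Walker — robust to the autocorrelation of thinned MCMC output,
unlike a short fixed-lag window). |z| < 2 is the convergence band; a fit
where no chain has all parameters inside the band is returned with an
explicit `converged = False`, never silently. Constant chains (pinned
variances) are excluded from the diagnostic, which is undefined for them.

## Selection-experiment mixed model

The artificial-selection data are cells from three treatments (small /
control / large selected), 12 lineages per treatment sampled at two
generation blocks (350 and 450 generations). The scaling exponent is
estimated by REML (statsmodels `MixedLM`):

    log10 N ~ log10 C + generation block
              + (random intercept + random slope | lineage-in-generation)

The random intercept and slope are correlated bivariate normal per
lineage-within-generation unit (unstructured 2 × 2; switchable to
independent). Treatment is deliberately *not* a fixed effect — the
question is the pooled scaling across the evolved size range — though the
cells carry the label. The slope CI is a Wald normal-approximation
interval, documented as an approximation. Optimisation runs BFGS and
Powell and keeps the converged fit with the higher REML likelihood:
gradient methods can stall short of a variance boundary (relevant when a
lineage variance is truly zero), while Powell finds the boundary, where
the model collapses exactly to OLS.

`partial_residual_points` subtracts the estimated block effect and the
BLUP lineage contributions from each cell. Because the mixed-model
residuals at the REML solution satisfy ε̂ = σ²V⁻¹(y − Xβ̂), they are
exactly orthogonal to the fixed-effect columns, so an OLS line through
the adjusted points reproduces the fixed slope to machine precision (and
the adjusted N:C slope reproduces b − 1) — the package's strongest
internal consistency check for this module, verified in the tests.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed); one master seed
streams per-component seeds through `numpy.random.SeedSequence`. Noise is
multiplicative log-normal (additive on log10 scales) throughout,
consistent with every analysis operating on log-transformed data.

**Trees**: a Yule (pure-birth) process, starting from two lineages at the
root, waiting Exponential(k·λ) while k lineages are extant, and appending
a final Exponential(n·λ) interval after the n-th lineage appears — so the
expected height is Σ_{k=2}^{n} 1/(kλ), the closed form the tests check by
simulation. **Traits**: Brownian motion down the tree (Normal(0, rate·ℓ)
increments per edge), giving tip covariance rate·A exactly.

**Among species**: one Yule subtree per clade grafted onto a shared root
with a 0.5 stem. log10 cell volume starts at a clade-specific root value
(defaults spread the nine clades across ~6 orders of magnitude, bacteria
near 1 μm³ to salamanders near 10⁴ μm³) and evolves by BM at rate 0.35
per unit branch length. The latent nucleus signal is
log10 a + b·log10 C + BM deviation (rate 0.08² — extra phylogenetic
covariance not explained by cell size). DNA content scatters around the
calibration-inverse of that latent signal (SD 0.12 — genuine
species-level variation in genome size at a given cell size), and the
*observed* nucleus volume sits on the calibration line (slope 1.03, clade
intercepts near 1.0–1.45 log10 μm³/pg) with iid residual SD 0.20. Two
consequences, both deliberate: the calibration fit recovers its own
generating slope and intercepts without errors-in-variables attenuation
(noise added to the regressor after inversion would bias the slope
downward and differently per clade), and with the default residual the
calibration R² on the log10 scale lands near 0.94 — the residual SD is
the knob that sets that figure and 0.20 was fixed for it. Defaults use
b = 0.7 and log10 a = −0.45 for every clade (N:C ≈ 4% at 10³ μm³,
declining with size).

**Within species**: log-normal cell volumes (defaults: mean 2.0, SD 0.5
on log10), power-law nuclei with residual SD 0.08. The containment
invariant nucleus < cell is enforced by resampling offending rows (up to
100 passes) rather than truncating, keeping the error model clean;
generating regimes that cannot satisfy containment raise with advice to
change parameters. Resampling introduces a truncation distortion only
when violations are frequent, i.e. only in regimes the error already
flags.

**Selection experiment**: treatment mean cell volumes default to the
study's printed 97 / 177 / 915 μm³; the log-normal location is shifted by
−ln(10)·σ²/2 so realized *arithmetic* means match those figures (the
large:small design ratio is 9.4). Twelve lineages per treatment per
generation block; 1,332 cells at generation 350 and 1,058 at 450, spread
evenly across lineages. Each lineage draws a cell-size offset (SD 0.05),
a random intercept (SD 0.05) and a random slope deviation (SD 0.03);
cells add log10 noise 0.06; the 450-generation block shifts log10 nucleus
by +0.04. The default exponent 0.52 with log10 a = −0.165 is derived from
the reported fall of the N:C ratio from ~7–8% in ~100 μm³ cells to ~2–3%
in ~1000 μm³ cells (b − 1 ≈ −0.48 over that decade); no within-experiment
exponent is printed to copy, so this anchoring is the package's choice.

The generators do **not** emulate: real taxon sampling or tree shape,
plot-digitization measurement error, erythrocyte biology or any
cell-type-specific effect, selection dynamics over generations (lineage
effects are drawn iid, not evolved), or non-log-normal noise. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed model, not robustness to real-data pathologies.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep the suite quick while
leaving Monte-Carlo error well inside the asserted bands: CI-coverage
studies use 200 replicates per estimator (binomial SE ≈ 1.5% at the 95%
nominal level) with planted b cycling through {0.58, 0.7, 1.0}; the
phylogenetic model runs on 24-species trees with nitt = 20,000 for these
studies, and the full 500,000-iteration retention check runs once on a
12-species tree; selection-experiment coverage uses 4 lineages per
treatment per block with 288 cells. The in-suite check of the selection
size ratio averages 10 seeded replicates, pinning its Monte-Carlo SE near
0.09 against a ±0.5 band — a deliberate check of the generator's
centering rather than of a single draw.

## Known limitations

* The phylogenetic sampler supports one observation per species
  (aggregate first) and a Brownian-motion covariance only — no Pagel's λ,
  no Ornstein-Uhlenbeck, no missing-response imputation.
* Calibration prediction intervals neglect the intercept–slope estimation
  covariance and carry no back-transform bias correction; downstream
  models consume point predictions, so calibration uncertainty is not
  propagated into among-species posteriors.
* The Wald CI for the selection-model slope ignores degrees-of-freedom
  corrections (Satterthwaite/Kenward-Roger); with ≥ 24 lineage units the
  undercoverage is small (measured ≈ 95% at the reduced test sizes).
* Major-axis CIs can be unbounded at weak correlation; this is reported
  honestly as an infinite bound rather than clipped.
* The pipeline's manifest hashes guarantee reproducibility on a fixed
  platform; floating-point results across BLAS builds may differ in the
  last digits.
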