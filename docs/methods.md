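# Methods

This note documents the models, numerical choices and design decisions
behind `methyldyn`, and what the synthetic cohort does and does not
emulate.

## The synthetic cohort

The generator produces a two-visit cohort ("S4" baseline, "F4" follow-up,
gap uniform on 7 ± 0.5 years) of current, former and never smokers
(CS/FS/NS) with baseline proportions 280:449:615 (≈ 21/33/46%), the
composition of the population study the analysis design is modeled on.
A baseline CS quits before follow-up with per-year probability
`quit_rate` (default 0.06, chosen so that roughly 181 of 280 baseline CS
remain CS over ~7 years). Former smokers receive a time since quitting
(TSQ) capped so follow-up TSQ stays within (0, 70] years. A configurable
small fraction of stable former smokers is given a corrupted follow-up
cessation age (to exercise the TSQ-inconsistency exclusion) or a
quit/restart/requit history (cessation age postdating the baseline
interview). Occasional smokers (5% of CS) are recorded at 0.5
cigarettes/day, the convention for analyses of intensity.

Covariates loosely match a middle-aged European population cohort:
age ~ N(55, 8.5²) (CS slightly younger), sex male-fraction 0.57/0.64/0.35
by CS/FS/NS, BMI ~ N(27.5, 4.5²), alcohol half-normal with scale
20 g/day, white-cell count ~ N(6, 1.5²), and five leukocyte proportions
(monocytes, B, NK, CD4, CD8) from a Dirichlet whose means sum with a
granulocyte remainder to 1. They are configurable, not fitted.

Latent methylation per site *s*, individual *i*, visit *j*:

```
M_sij = baseline_s + Σ_c γ_sc x_cij + μ_si + δ_s g_ij + b_s,batch(ij) + ε_sij
```

* `baseline_s`: bimodal (≈45% near M=−3, 45% near +3, 10% intermediate),
  as on real arrays.
* `γ_sc`: per-site covariate coefficients, N(0, scale_c) with cell-type
  proportions given the largest scale — cell composition dominates real
  whole-blood methylation variation.
* `μ_si ~ N(0, σ²_μ)`: the individual random intercept. Intercepts are
  drawn independently **per site** (a sites × individuals matrix): the
  analysis fits each site's mixed model independently, and independent
  intercepts keep per-site fits statistically independent across sites,
  which the calibration checks rely on. A single intercept shared across
  all sites would induce cross-site dependence that no per-site model
  addresses.
* Smoking term `δ_s g_ij`: δ_s ~ N(−0.8, 0.4²) on the M scale with
  |δ_s| ≥ 0.3 at the `n_affected_sites` affected sites (negative
  location: smoking predominantly lowers methylation at associated
  sites), zero elsewhere. For current smokers
  `g = 1 + 0.02·(cigs/day − 15)` — intensity enters linearly, matching
  the linear intensity model fitted downstream; saturation of the dose
  response at heavy exposure is *not* modeled (documented limitation).
  For former smokers at reversible sites `g = exp(−TSQ/τ)` with shared
  timescale τ = 10 years — the simplest mechanism consistent with
  reversion rates proportional to the initial disturbance; a configurable
  fraction (default 20%) of affected sites is persistent (no decay).
* `b_s,batch`: an additive per-(site, batch) technical shift,
  N(0, 0.2²·batch_shift_scale). The same batch assignment shifts the
  control-probe intensities (probe-specific shifts of SD
  150·batch_shift_scale against probe noise SD 50), so the batch is
  *expressed in* the control probes and removable by control-probe PCA;
  `batch_shift_scale = 0` switches all batch structure off.
* `ε_sij ~ N(0, σ²_ε)`; defaults σ_μ = σ_ε = 0.25 M-units.

β-values are the inverse logit (base 2) of M. Detection p-values, bead
counts, planted detection failures (p ≥ 0.01 at `missing_rate`), low bead
counts, and gross outliers (≥ 6 total-SD displacements at `outlier_rate`)
are attached. A ~1% fraction of sites is flagged as SNP probes and ~3%
placed on chrX/chrY to exercise the probe filters; affected sites are
always autosomal non-SNP so filters never remove planted signal.

**What the generator does not emulate:** probe-type (Infinium I/II)
chemistry, fluorescence backgrounds, genetic effects on methylation,
dose-response saturation, cohort attrition/selection, or any empirical
distribution of real effect sizes (none is published; the effect-size
distribution is a free parameter). Passing tests therefore demonstrate
correctness of the *analysis machinery* under a plausible generative
model, not performance on real cohort data.

## Preprocessing

Fixed order: SNP-probe removal → entry filters (detection p ≥ 0.01 or
beads ≤ 3 set missing; samples with detection rate ≤ 0.95 dropped — both
boundaries inclusive) → per-visit site filters (non-missing rate < 95% in
either visit, or chrX/Y, removes the site) → quantile normalization →
β→M logit transform → control-probe PCA technical adjustment. The scale
tag on the container records the stage and re-processing is refused.
Because the generator emits β-values directly (no fluorescence model),
quantile normalization operates on β rather than raw intensities, and
background correction is reduced to an optional fixed-offset subtraction.
Normalization is unstratified by probe type (no probe chemistry is
simulated); the reference distribution is the across-sample mean of
sorted vectors, ties share the mean reference over their rank span, and
missing entries are excluded and restored.

Technical adjustment: control probes are centred per probe (not
variance-scaled); sample-wise PCs are right singular vectors, each PC's
sign fixed by making its largest-magnitude loading positive. Per site, M
is regressed on an intercept, the first 20 PCs (fewer if the sample or
probe count requires) and batch-indicator dummies; residuals are the
adjusted values. A batch indicator collinear with the PCs is dropped with
a warning. Directions with zero singular value are never used as
regressors.

Outlier removal (per analysis, per site): OLS of the value vector on the
model's fixed-effect design, residual SD with denominator (n − rank),
entries beyond 5 SD marked, at most 5 removed (largest |residual|
first), single pass without refit — iteration is deliberately not
performed. The pooled two-visit design with the time-passed variable is
used for the confounder-residualization and outlier regressions.

## Phenotype derivation

TSQ = interview age − cessation age (0 allowed arithmetically, excluded
from categories); duration = initiation→interview (CS) or
initiation→cessation (FS); occasional smokers are CS at 0.5
cigarettes/day. Former smokers are excluded for missing TSQ, for a
quit/restart/requit history between visits, or for inconsistent TSQ:
follow-up TSQ deviating from (baseline TSQ + gap) by **more than 5 years
and more than 20%** — the conjunctive reading of the rule; a disjunctive
variant is available behind a flag for sensitivity analysis.

TSQ_L categorization rounds TSQ half-up to integer years (ages are
integer-reported) and uses half-open (low, high] intervals. `matched`
mode places integer breakpoints greedily so category counts are as equal
as possible (ties toward the earlier boundary). `fixed` mode defaults to
breakpoints 4, 14, 21, 27 for the first four categories — the published
interval labels — with the later bounds (35, 45) being package defaults,
not published values.

## Association models

EWAS: baseline visit, CS and NS only; per-site OLS of adjusted M on
smoking status, age at interview and the confounders (sex, alcohol, BMI,
white-cell count, five cell proportions); two-sided t test; Bonferroni
threshold α/m with m the number of sites actually tested — always
recomputed, never hard-coded. Sites with under 10 observations per group
are reported missing. Per-site OLS and residualization use vectorized
linear algebra rather than a per-site model object, for speed; the mixed
model is cross-checked against an independent implementation in the test
suite.

Longitudinal models share one design: intercept, category indicators,
age at baseline, time passed (0 at baseline), category × time
interactions, confounders; individual random intercept. The displayed
model carries a single shared β_t for the reference with interactions as
deviations, implemented literally. Cross-sectional models use age at
interview; longitudinal models use age at baseline plus time passed.
Aliased design columns are dropped and reported; sites whose fits fail
are reported missing rather than silently dropped; categories with fewer
than 5 individuals are retained but flagged low-n.

REML: the restricted likelihood is profiled over λ = σ²_μ/σ²_ε. Groups
(individuals) have 1 or 2 rows; an orthogonal within-pair transform (sum
and difference over √2) diagonalizes the covariance with weights
1/(1 + mλ) on group-mean rows, so the weighted cross-products decompose
into three precomputed matrices and each likelihood evaluation is O(p²).
log λ is scanned on a 41-point grid over [−12, 12], refined by bounded
scalar minimization, and compared against the explicit λ = 0 (OLS)
boundary. Fixed effects and their covariance come from GLS at the
optimum. Satterthwaite df per coefficient use central finite differences
of the coefficient variance and of the REML deviance Hessian in
(σ²_μ, σ²_ε); at the boundary the OLS residual df is used, and
non-positive df fall back to the normal approximation with a warning.

## Dynamics

Per-individual change = follow-up − baseline of confounder-residualized
β-values (any per-site constant cancels). Former smokers are binned by
TSQ at follow-up in half-open 2-year intervals (or TSQ_L categories);
NS-NS and CS-CS are reference bins. Medians and IQRs use
linear-interpolation (type-7) quantiles. The dynamism IQR is reported
missing for bins with fewer than 4 sites **or fewer than 10 contributing
individuals** (default): a "median change" over one or two people is
dominated by individual noise, and without a minimum occupancy the
across-bin comparison is driven by the emptiest bins; the published
version of this curve was read off a loess smoother, which this package
treats as cosmetic and does not implement. Zero median changes are
excluded from consistency proportions (sign(0) is undefined). The
diverging/converging classification compares |group median − reference
median| at follow-up vs baseline; exact ties are labelled converging
with a tie flag. The NS-NS reference change is a single pooled bin.

## Problem sizes and checks

The test-suite simulations use cohorts of 120–600 individuals and
120–550 sites per seed (1344 — the full-cohort scale — for the dynamism
property, where tail bins must be populated), sizes at which every
planted property is comfortably detectable. The acceptance script runs
the full pipeline at 600 individuals × 1000 sites. The REML estimator is
verified against an independent dense-covariance 2-parameter maximizer
on 100 small instances (≤ 1e-6 in log-likelihood), against statsmodels'
mixed-model implementation on a larger instance, and by type-I
calibration (nominal 5% test rejecting at 3.5–6.5% over 1000 null
site-fits) and parameter recovery (planted coefficients within 2 SE on
average over 50 seeds).

## Known limitations

No probe-chemistry simulation or EPIC/27K support; no random slopes or
GEE alternatives; no per-site decay-rate estimation (only the
correlation diagnostics); pack-years is exposed only as an optional
covariate, not a validated analysis; the intensity model is linear (no
saturation); enrichment analyses against external databases are out of
scope.
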