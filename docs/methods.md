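# Methods

## The problem

MALDI-TOF/MS peptidomic profiling produces, per spectrum, a vector of peak
intensities at aligned m/z positions (here the 1000–4000 Da window).  Two
obstacles stand between those intensities and a credible biomarker claim:

1. **Measurement error.**  Signals are label-free and only
   semi-quantitative; replicate measurements of the same subject differ
   substantially (intra-assay CVs above 20% are typical).  In a logistic
   regression of disease on a noisily measured feature, classical
   measurement error attenuates the slope toward the null, so naive
   screens understate real associations.
2. **Left-censoring.**  Weak peaks fall below the instrument's signal
   limit of detection (sLOD) and are recorded as missing or as noise-level
   values, which biases both variance estimates and regressions.

`peptivar` implements the statistical chain that addresses both: LOD-aware
normalization, variance-component estimation of the error structure,
Monte Carlo validation of that error structure under censoring, and
error-corrected association testing.

## Models and estimators

### Error model

All modelling is done on a log scale, where the multiplicative error model
for an observed intensity W of subject i, replicate j becomes additive:

    log W_ij = x_i + eps_ij,
    x_i   ~ N(mu, sigma_b2)   (true subject level, between-subject)
    eps_ij ~ N(0, sigma_w2)   (replicate deviation, within-subject)

The reliability of a single measurement is the intraclass correlation
coefficient ICC = sigma_b2 / (sigma_b2 + sigma_w2), which is also the
attenuation factor of a naive regression slope under this model.  The
data-analysis pipeline uses log2 (the sLMNLT convention); the Monte Carlo
reliability study uses natural logs, the standard scale on which the
multiplicative model's error variances (0.01–0.64 here) are quoted, so
that the raw-scale "LOD/2" substitution is a `c − ln 2` shift of the log
value at censoring point c.

### sLMNLT normalization (`peptivar.preprocessing`)

Order: sLOD adjustment → per-spectrum median normalization → log2.

* **sLOD estimation**: `mean(noise) + k·SD(noise)` over pooled noise-region
  intensities, `k = 3` by default.  The rule is a package declaration (the
  classical blank-based detection-limit construction); `k` and per-feature
  vs global thresholds are configurable, global is the default.
* **Below-LOD substitution**: `lod_half` (sLOD/2, the default), `zero`
  (kept for comparison; documented pathology: breaks the log step),
  `richardson_ciampi` (E(W|W<sLOD)) and `schisterman` (E(W|W>sLOD) — it
  conditions on the *upper* tail; implemented literally as published and
  flagged here because it is an unusual construction).  The conditional
  expectations use a log-scale normal model with plug-in mean/SD from the
  uncensored cells of each feature; a censored-data MLE was considered and
  rejected as unnecessary for the fill-value role the quantity plays.
* **Median normalization** divides each spectrum by its own median over
  non-missing features (median exactly 1 afterwards); creatinine
  normalization divides urine spectra by urinary creatinine (mmol/L).
* State tags on the table (`raw → lod-adjusted → median-normalized →
  log2`) make it an error to run a stage twice or out of order.

Feature matching across matrices (urine vs serum) is greedy one-to-one
nearest-neighbour matching within an m/z window (default 0.3 Da), smallest
|Δm/z| first, ties to the lower m/z.

### Variance components and ICC (`peptivar.variability`)

One-way random-effects ANOVA with method-of-moments estimators, valid for
unbalanced subject groupings: `sigma_w2 = MSW`,
`sigma_b2 = (MSB − MSW)/n0` with `n0 = (N − Σni²/N)/(k−1)`.  Negative
between-subject moment estimates are clipped to zero and flagged rather
than smoothed away by REML — the classical estimator is transparent and
exactly testable against hand ANOVA arithmetic.  The ICC interval is the
F-based (Searle) form with `n0` standing in for the common group size;
simulated coverage at ICC 0.5 with 20 subjects × 3 replicates is within a
few points of nominal (the acceptance script recomputes it).

Spot-level replicates are averaged per sample before the subject-level
ANOVA, so the two reported components are subject-vs-sample level; a
three-level decomposition is deliberately out of scope.

Assay precision uses the same machinery one level down (runs × replicate
spots, default 5 × 5): `intra CV = 100·sqrt(sigma_rep2)/mean` and
`inter CV = 100·sqrt(sigma_run2 + sigma_rep2)/mean` on the normalized,
pre-log intensity scale.  Feature summaries (median, IQR) use type-7
quantiles so they are reproducible across environments.

### Monte Carlo reliability of the ICC (`peptivar.lod_simulation`)

Grid: error variance sigma_eps2 ∈ {0.01, 0.04, 0.09, 0.16, 0.25, 0.36,
0.49, 0.64} × censoring fraction ∈ {0.125, 0.25, 0.50} (0 allowed as an
uncensored baseline) × the four substitution strategies.  Within a
simulation, all strategies see the same data and the same threshold (set
at the empirical marginal quantile, so target fractions hold exactly in
expectation), making strategy contrasts paired.  Defaults: 20 subjects ×
3 replicates, sigma_b2 = 0.345 — chosen so the uncensored ICC spans ≈0.97
at the smallest error variance down to ≈0.35 at the largest, the range the
reliability narrative describes; the value is configurable and not claimed
to be the original study's (those design constants were never published).
Whether the quoted error grid indexes sigma or sigma² is ambiguous in the
source material; it is treated as a variance, configurable.

"Strategy A behaves like strategy B" is judged against the estimator's own
Monte Carlo dispersion (SD of the ICC estimate across simulations, ≈0.03–
0.15 for a 20×3 design), not against the standard error of the mean: the
strategies differ by small *fixed* biases (measured ≤ ≈0.03 in mean ICC at
12.5% censoring, vanishing as error variance grows), and a fixed bias can
never sit inside a band that shrinks with the number of simulations.  On
that scale, LOD/2 substitution is indistinguishable from the uncensored
estimator below 50% censoring and from Richardson–Ciampi below 25%, while
zero-substitution is catastrophic at any censoring level — which is the
practical message of the study.

### Error-corrected logistic screening (`peptivar.association`)

The logistic likelihood is maximised by Newton/IRLS (tolerance 1e-8, max
50 iterations) written in-package because the fitting contract — exact
tolerance, iteration cap, separation flagging — is part of the module's
interface; `statsmodels.Logit` serves as an independent cross-check in the
test suite.  Separation is flagged when the linear predictor perfectly
classifies the outcome at a large margin; flagged fits are excluded from
screens rather than reported.

* **RCAL**: `beta* = beta_naive / ICC`; the confidence interval divides
  the naive Wald endpoints by the same ICC (Rosner's construction).  The
  correction can only move a coefficient away from zero (|beta*| ≥
  |beta_naive| for 0 < ICC ≤ 1).
* **SIMEX** (Cook–Stefanski): for λ ∈ {0.5, 1.0, 1.5, 2.0} (default),
  B = 100 refits with added N(0, λ·sigma_w2) predictor noise; the
  per-λ mean coefficient, anchored by the naive fit at λ = 0, is
  extrapolated quadratically to λ = −1.  Variances use the difference
  method (mean model-based variance minus between-simulation variance of
  the coefficients), extrapolated on the same grid.  The quadratic
  extrapolant is known to under-correct for logistic models — in the
  package's own simulations it recovers roughly 60–80% of the attenuation
  gap where RCAL recovers it essentially fully.  That asymmetry (RCAL
  correcting more than SIMEX, most visibly when the ICC is small) is a
  property of the methods, not a defect, and is asserted as such in the
  tests.
* **Screens**: one predictor + intercept per feature (no covariate
  adjustment), feature-specific ICC / sigma_w2 where estimable and the
  median over estimable features otherwise, Benjamini–Hochberg step-up
  adjustment across all screened features (delegated to
  `statsmodels.stats.multitest` behind the `bh_adjust` surface).  A joint
  multivariate fit of a selected feature set is provided, with collinear
  sets rejected by rank check rather than silently ridged.
* **Group assignment** maps biopsy histology to the two-group contrast
  (Reference = no alteration/BPH/inflammation vs cancer lesions =
  PCa/HGPIN/ASAP, AAH excluded) or the four-group A/B/C/D scheme.

### Diagnostics (`peptivar.diagnostics`)

AUC is the Mann–Whitney statistic (ties count half) with a DeLong
placement-variance interval; an exhaustive pair-enumeration oracle backs
it in the tests.  Cutoff sensitivity/specificity use Clopper–Pearson exact
intervals; likelihood ratios use log-method intervals, with perfect
specificity reported as LR+ = ∞ and a one-sided interval.  Marker
direction (e.g. f/tPSA *lower* in cancer) is always an explicit argument.
The PCA3 score is PCA3 mRNA / PSA mRNA × 1000.

## What the synthetic data emulates — and what it does not

The generators (`peptivar.synthetic_data`) reproduce the statistical
skeleton the analysis relies on: log-normal intensities with subject- and
replicate-level log-scale variance components (urine-like defaults
sigma_w2 = 0.184, ICC ≈ 0.48, via sigma_b2 = 0.170; unbalanced 16×2 + 4×3
sampling with quintuplicate spots; a 5×5 precision design), left-censoring
at an intensity threshold or a target marginal quantile, and a
case-control cohort (default 70 cases / 76 controls, plus optional
AAH-labelled subjects that group assignment excludes, mirroring the
146-of-148 cohort arithmetic) whose disease status depends on the *true*
feature levels — the classical-error assumption RCAL/SIMEX need.
Phenotype covariates (age, PSA fractions, PCA3 score, creatinine) are
drawn from cohort-flavoured log-normals with the case/control contrasts
running in the clinically observed directions.

Not emulated: raw continuous spectra (peak shapes, baselines, adducts),
instrument drift, feature-wise correlation structure, and any real
biological pathway signal.  Passing tests therefore demonstrate that the
*estimators* behave as claimed under the assumed error model, not that any
particular peptide is a prostate-cancer biomarker.

## Numerical choices and degenerate inputs

* Logistic IRLS clips linear predictors at ±500 and floors weights at
  1e-12; singular information matrices surface as flagged fits.
* Truncated-normal fill values guard against tail underflow by returning
  the censoring point itself when the tail probability underflows to 0.
* Substitution with fewer than two uncensored donor values per feature
  falls back to sLOD/2.
* `n0`-based unbalanced ANOVA reduces exactly to the balanced formulas
  when group sizes are equal; all-singleton designs raise.
* Zero sample medians, zero/missing creatinine, non-positive cells before
  log2, unknown histology labels and out-of-range p-values all raise
  errors naming the offending sample/label.

## Problem sizes used by the tests and the acceptance script

Attenuation/recovery: 200 cohorts of 2000 subjects (plus one 4000-subject
SIMEX run at B = 100).  ICC calibration: 1000 one-way designs of 20×3.
LOD study: the full 8×4×4 grid at 200 simulations per cell.  BH screen:
200 cohorts of 200 subjects × 100 features (5 with real effects).  These
sizes give Monte Carlo standard errors an order of magnitude below the
asserted tolerances while keeping a full run in tens of seconds.

## Known limitations

* REML/Bayesian variance components, crossed designs and covariate-
  adjusted or penalized disease models are out of scope.
* The quadratic SIMEX extrapolant's under-correction is reported, not
  repaired (the rational-linear extrapolant would narrow it).
* Richardson–Ciampi/Schisterman fills use plug-in parameters from the
  uncensored cells, which are right-truncated; at heavy censoring the
  plug-in mean is biased upward and the fills inherit that bias.
* The Monte Carlo study's design constants (sigma_b2, cohort sizes) are
  package defaults chosen to match the published narrative's endpoints,
  not recovered study parameters; cell-level agreement with the original
  simulation tables is out of scope.
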