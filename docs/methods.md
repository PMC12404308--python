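# Methods

## The estimand

For a binary health indicator and an ordered socioeconomic dimension
(schooling in six levels, per-capita income in five minimum-wage
bands), the slope index of inequality (SII) and relative index of
inequality (RII) summarize the *entire* socioeconomic gradient rather
than comparing two extreme groups. Individuals are ranked from 0 to 1
by ascending socioeconomic position through the Ridit score of their
category — the midpoint of the cumulative population share,
s_k = F_{k−1} + f_k/2 — so the indices are sensitive to how the
population is distributed across categories, not just to category
labels. SII is the absolute difference (reported in percentage points)
and RII the ratio of the model-predicted prevalences at rank 1 versus
rank 0.

## Estimation

**Ridit scores** use survey-weighted category shares, computed
separately within each survey year by default: each edition's
population defines its own 0–1 ranking, which matters when the SES
distribution shifts between editions. Pooled scoring across years is
available as a switch (`per_year_ridit=False`). Zero-mass categories
are dropped with a warning; shares off 1 by more than 1e-6 are an
error, smaller discrepancies are renormalized.

**Regression.** The gradient model is a weighted Poisson
(pseudo-likelihood) regression with log link of the outcome on the
Ridit score, sex, age group (18–29 / 30–59 / 60+), a year main effect,
and optionally a Ridit × year interaction. A log-link model on a binary
outcome estimates prevalence ratios directly and makes the RII a simple
function of the gradient coefficient. Point estimation is IRLS
(statsmodels GLM, deviance tolerance 1e-10); the covariance is computed
in-package as a sandwich estimator whose meat is the stratified
between-PSU covariance of the weighted score contributions,

cov = Σ_h n_h/(n_h−1) Σ_j (t_hj − t̄_h)(t_hj − t̄_h)ᵀ,

with t_hj the score total of PSU j in stratum h — the same Taylor
linearization used for the prevalence estimator, so clustering and
stratification enter both stages consistently. This was checked
numerically against an independent sandwich implementation
(R `sandwich::vcovCL`) and the frozen reference values live in the test
suite. Strata left with a single PSU are collapsed into the adjacent
stratum (by sorted label) with a logged warning.

**Prediction at the extremes.** Covariates are handled by marginal
standardization (g-computation): the fitted prevalence is averaged,
with survey weights, over the observed covariate distribution of all
analysis rows, with the Ridit fixed at 0 or 1 and the year fixed at the
target year. Under the log link the covariate factors cancel in the
ratio, so RII = exp(β_ridit + β_interaction[year]) exactly — an
identity the tests verify to 1e-10 — while the SII is a genuine
population-averaged difference. Standardized predictions can exceed 1
for steep gradients on common outcomes; this log-link artifact is
recorded as a warning on the estimate, not an error. The alternative —
fixing covariates at reference levels — would report a
reference-pattern SII instead of a population-averaged one; the
population-averaged choice matches how prevalences are reported.

**Uncertainty.** The SII interval uses the delta method on the
standardized difference (gradient: weighted average of μ·x at each
Ridit extreme); the RII interval is symmetric Wald on the log scale,
guaranteeing a positive lower bound. Prevalence CIs are computed on the
logit scale and back-transformed so that bounds stay inside [0, 1] even
for indicators near 97–98%.

**Trend rule.** A Ridit × year interaction is fit first and kept only
when its cluster-robust Wald test has p < α (strict; default α = 0.05,
joint chi-square when more than two years are present). When dropped,
the final model has one pooled gradient and the yearly indices differ
only through the year main effect (identical RIIs by construction).
The year comparison of raw prevalences is a design-based Wald
chi-square on the prevalence difference with linearized variances, the
standard survey analogue of a 2 × 2 chi-square test; a Rao–Scott
corrected Pearson test would be an equally defensible choice and the
code isolates the test behind `year_comparison_test` so it can be
swapped.

## The synthetic-data generator

`simulate_survey` emulates the design features that drive inference in
a national household survey: strata containing equal numbers of PSUs,
respondents nested in PSUs, log-normal sampling weights with a
configurable coefficient of variation (default 0.5) normalized to mean
1 per year, SES categories drawn from fixed marginal proportions
(defaults: the six schooling shares 8.3/30.7/9.9/5.6/28.1/17.4% and
five income shares 49.7/28.8/9.4/6.4/5.7% typical of the adult
Brazilian population), sex (47.1% male) and three age bands
(26.1/55.8/18.1%). Outcomes follow
log p = log p0 + β·ridit + sex effect + age effect + u_PSU with
u_PSU ~ N(0, σ²) (default σ = 0.05) inducing positive intra-cluster
correlation so that cluster-robust variances are genuinely exercised.
Default nuisance effects are mildly negative (sex −0.10; age −0.10,
−0.30) so that adjustment has something to adjust for. Configurations
implying p > 1 anywhere — including after the PSU perturbation — are
rejected outright rather than clipped, because clipping would bias the
true SII.

**Closed-form truth.** RII_true = exp(β) (covariate and PSU factors
cancel in the ratio). SII_true is the *population-averaged* value
100·p0·(exp β − 1)·E[exp(covariate effects)]·exp(σ²/2), which is what
the marginal-standardization estimator targets; with all nuisance
effects at zero it reduces to 100·p0·(exp β − 1). Truths are per year
when β varies by year.

**What the generator does not emulate:** household rosters,
nonresponse, post-stratification calibration, informative sampling
(weights are independent of outcomes), or correlation between the two
SES dimensions. Passing recovery tests therefore show correctness of
the estimation machinery under a correctly specified design, not
robustness to those real-data features.

## Validation design and problem sizes

- Exact oracles (< 1 s): hand-computed Ridit scores; Horvitz-Thompson
  on a 4-row toy; SII/RII against the two-point log-linear closed form
  on 2–3 equal-weight categories with one PSU per row.
- Identity checks: RII vs exponentiated gradient to 1e-10 on 100 random
  small fits (400 respondents/year).
- Recovery: 50 replicates of 20,000 respondents/year (25 strata × 8
  PSUs × 100), true RII 2.0 / SII 30 pp; mean recovery and 95% CI
  coverage for both indices.
- Calibration: 200 null replicates of ~2,000 respondents/year across 90
  PSUs/year for the interaction-retention rule and the year-comparison
  test. Calibration is driven by the number of clusters, so the smaller
  per-replicate sample keeps the check sharp while cheap.

## Numerical and degenerate-input choices

- Weighted prevalences and SII/RII are invariant to global weight
  rescaling and row order (tested).
- A constant outcome aborts the fit with a clear error; non-converged
  fits are flagged and refused by downstream index computation.
- Domain (subgroup) variances keep all PSUs in the design, with zero
  contributions outside the domain; domains covered by fewer than two
  PSUs are flagged with an undefined SE.
- Respondent-level missing outcomes are excluded per outcome
  (complete case); exclusion counts are logged per outcome with a
  machine-readable reason code in the run metadata.
- "Intercept-only" mean reproduction is verified through the score
  equation (the weighted mean of fitted prevalences equals the weighted
  sample prevalence to 1e-8); the gradient model always carries the
  Ridit term, so a literal intercept-only fit is outside its surface.

## Known limitations

- Variance estimation assumes with-replacement PSU sampling within
  strata (no finite-population correction) and ignores weight
  calibration; replicate-weight methods (BRR/jackknife) are out of
  scope.
- The log link can predict above 1; estimates are still reported (with
  a warning) because the indices are functions of two standardized
  means, but steep gradients on very common outcomes deserve a check of
  those warnings.
- The trend rule is a binary retain/drop decision at a fixed α; no
  model averaging or shrinkage across editions.
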