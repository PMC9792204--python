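# Methods notes

This note documents the statistical procedures grimclock implements, the
defaults it chooses where the literature is silent, and what the synthetic
cohort does and does not establish about behavior on real data.

## Stage 1: surrogate biomarkers

Each surrogate regresses a plasma analyte on all CpG beta values plus
chronological age and a female indicator, all as *penalized* candidates.
Target preprocessing follows the convention for right-skewed analytes:

- **Winsorization** is upper-tail only. The cap is the largest raw value
  whose scaled value (x − mean)/SD, computed once on the raw vector with the
  n−1 SD, is ≤ 6; larger values are replaced by the cap. The observed
  minimum is stored as a lower bound and used only to clamp prediction-time
  inputs to the training range. The published training bounds for the two
  flagship analytes (CRP 0.14–54.01 mg/L, A1C 4.7–10%) ship as constants.
- **Log transform** is natural log, applied after winsorization.

The elastic-net objective is MSE/2 + λ[α‖β‖₁ + (1−α)‖β‖₂²/2]. Predictors
are standardized internally and coefficients reported on the original
scale. λ is selected at the minimum of k-fold cross-validated MSE (not the
one-SE rule) on a shuffled, seed-fixed fold assignment without
stratification; α defaults to 0.5 — the ridge/lasso midpoint conventional in
methylation-clock work — and is configurable. λ = 0 falls back to the exact
least-squares solution. The per-SD scaling of a surrogate uses the mean and
n−1 SD of its in-sample predictions, stored in the model file together with
per-CpG training means so that missing CpGs can be mean-imputed at
prediction time (a model without stored means refuses to predict through
missing CpGs).

## Stage 2: mortality clock

The clock minimizes the negative Breslow partial log-likelihood plus the
same elastic-net penalty, via a glmnet-style coordinate-descent path
(λ reported on the per-observation scale that software family uses).
Cross-validation scores each λ by the grouped partial-likelihood deviance
(Verweij–van Houwelingen): the full-data log-likelihood at the
leave-fold-out coefficients minus the training-fold log-likelihood, summed
over folds. λ = 0 falls back to an unpenalized Newton fit. Candidate λ
values where the path terminated early in some fold are excluded from the
comparison. On small cohorts with weak signal the CV optimum can be the
fully shrunk null model; the pipeline then raises rather than calibrating a
constant, since a zero-variance linear predictor has no year scale.

**Calibration** is the affine map with slope sd(age)/sd(xᵀβ) and intercept
mean(age) − slope·mean(xᵀβ), both with n−1 denominators, so the calibrated
training values match the training ages' mean and SD exactly. The age
column supplied is used as-is (a single measurement; no averaging of
repeated exams). The model fits standard right-censored data; left
truncation of follow-up is not modeled.

**Age acceleration** is the OLS residual of a clock (or any DNAm measure)
on chronological age; by construction it has mean zero and zero sample
covariance with age. **mortality.res** deviance residuals use the Breslow
cumulative baseline hazard estimated from the supplied linear predictors;
martingale residuals sum to zero whenever at least one event exists, and an
all-censored input returns a zero vector with a warning.

The published 12-covariate clock is packaged with its printed coefficients
and calibration constants. It operates at the component level: users supply
the ten DNAm component values themselves, because the per-CpG weights
behind those components were never published and are not bundled.

## Validation statistics

- **bicor** uses c = 9 with the raw (unscaled) median absolute deviation;
  observations at |u| ≥ 1 get zero weight. A zero MAD falls back to the
  standard deviation with a warning.
- **Fixed-effect meta-analysis** pools by inverse variance. Correlation
  strata are pooled on the Fisher-z scale with variance 1/(n−3) — the
  variance-stabilized choice — and the pooled estimate is back-transformed
  to a correlation for reporting; se/z/p remain on the z scale.
- **Stouffer** combines per-stratum Z scores weighted by √n.
- **Stratified association models**: Cox fits use lifelines (Efron tie
  handling; immaterial for continuous times) with the Huber sandwich
  cluster-robust variance when a cluster column (pedigree, subject) is
  given; explicit mixed models and GEE are deliberately not used.
  Logistic fits use statsmodels.
- **EWAS**: each CpG is screened after one-pass six-SD extreme masking
  (moments computed once on the unmasked vector; re-running with recomputed
  moments could mask more — the one-shot rule is intentional). The numeric
  trait screen reports Pearson r with a Student-t p (df = n−2) and
  Z = atanh(r)·√(n−3); the censored-trait screen fits one Cox model per CpG
  under adjustment Model I (age, sex), II (+ pack-years), or III (+ seven
  blood-cell covariates, arbitrary column names accepted). P-values are
  unadjusted by default; Bonferroni/BH columns are available via
  `adjust_pvalues`.
- Two-sided p-values throughout; normal reference for pooled statistics.

## Synthetic cohorts

The generator emulates the covariance structure the two stages assume, at
the scale of the original training cohort (default n = 1833, age
66.1 ± 9.06 years, 13% deaths; p defaults to 1030 CpGs and is scaled down in
tests for speed — unit tests use p = 50–200, the heaviest recovery checks
n = 2000, p = 500). Ages are affinely standardized so the *empirical* mean
and SD equal the requested values. CpG logits combine a per-CpG baseline, a
small age loading, a latent per-analyte factor over 20 causal CpGs each,
and Gaussian noise; betas stay strictly inside (0, 1) and the generator
errors if more than 5% of logits exceed ±8 (saturation). Analyte signals
are linear combinations of their causal CpG betas plus age and sex, with
noise sized so the structural part explains 80% of variance; the CRP-like
analyte is exponentiated to produce the right skew that motivates
winsorization, and pack-years are zero-inflated (≈50% never-smokers, gamma
tail). Survival is Weibull proportional hazards (shape 1.5, so the hazard
rises with time rather than being memoryless) with log hazard linear in the
standardized log-analyte signals, age, sex and pack-years; censoring is
independent uniform with its upper limit tuned by bisection so the realized
event fraction hits the target within sampling granularity.

What passing tests show: the estimators recover known linear structure,
the solvers agree with independent textbook implementations, screening
p-values are calibrated under an exact null, and the calibration identity
holds. What they do not show: robustness to array batch effects, cell-type
composition confounding, pedigree correlation, non-linear CpG–analyte
relationships, or distribution shift between cohorts — none of which the
generator simulates.

## Numerical and interface choices

- SDs use the n−1 denominator everywhere a convention was needed
  (winsorization scaling, extreme masking, calibration, surrogate scaling).
- Extreme masking with zero SD returns the input unchanged; winsorization of
  a constant vector returns it with lo = hi.
- Model files are a small JSON dialect with a `model_type` tag; unknown
  fields warn, missing required fields fail, truncated files fail with a
  parse error.
- Matrices are samples × CpGs; a first column of `cg`-style IDs triggers a
  transpose error rather than a silent misread.
- One master seed drives every stochastic stage; stage seeds derive from it
  via a CRC so independent stages never share streams.

## Known limitations

- Exact replication of the original clock's selected CpG counts is not
  possible: the mixing parameter, λ grid and fold seeds of the original fits
  were never published, and the per-CpG weights of the legacy surrogates are
  in unpublished supplementary material. The framework trains any analyte
  supplied instead.
- The Stage-2 deviance criterion is one defensible choice; optimizing
  C-index instead can pick a different λ.
- Cluster-robust errors approximate, but are not identical to, mixed-model
  or GEE inference on pedigree data.
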