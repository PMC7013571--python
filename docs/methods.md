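# Methods

This note records the scientific and numerical choices behind `myoscreen`:
what each stage assumes, which knobs matter, what the synthetic cohorts do
and do not emulate, and where the design was genuinely open.

## Synthetic cohort model

The generator emulates a school-screening cohort followed from grade 1 to
grade 6. Each student *i* carries one latent standardized trait `u_ik` per
factor *k*; the observed per-grade factor values are monotone mappings of
the trait plus year-to-year jitter (0.3 trait-SD by default): behaviour
frequencies become clipped rounded counts or yes/no flags, ocular
measurements become clinically scaled continuous values (axial length in
mm around 23–24, keratometry around 43 D, pulse around 85–95), and
objective attributes (gender, number of bespectacled parents) are drawn
once and held fixed.

Refraction follows a smooth per-student trajectory with per-visit
measurement error:

    RA_ig = base_i + (g − 1)·Δ_i + e_ig,
    Δ_i   = drift + Σ_k β_k·u_ik,          e_ig ~ N(0, noise_sd²),

with `base_i ~ N(+0.5 D, 0.5 D)` (mildly hyperopic grade-1 children),
`drift = −0.15 D/yr` and `noise_sd = 0.25 D/yr`. These defaults give a
grade-6 myopia prevalence (RA ≤ −0.5 D) of ≈ 0.4–0.46, matching the
population this kind of cohort samples. An earlier random-walk variant
(noise accumulating along the trajectory) was rejected because the
accumulated noise appears both in the grade 1–5 slope feature and in the
grade-6 outcome, making even an effect-free cohort predictable; with
independent measurement error a null cohort is genuinely unpredictable
(AUC ≈ 0.5), which is the property the validation suite relies on.

Effect sizes `β_k` are signed diopters/year per trait SD; positive pushes
towards hyperopia (protective), negative towards myopia. The default
pattern plants the direction structure reported by the multivariate screen
of the motivating study — parental glasses, gender, indoor/outdoor
activity, axial length, corneal curvature, white meat and eggs protective;
near/far adjustment ability, pulse, cola and red meat adverse. (The axial
length and curvature directions are that study's finding, not a clinical
claim; the generator plants whatever pattern it is asked to.) Two presets
exist: `default_effect_sizes()` (|β| 0.03–0.10) and `strong_effect_sizes()`
(every planted |β| ≥ 0.075 = 0.3 noise-SD, up to 0.15), the latter defining
the planted-signal condition used by the power, recovery and end-to-end
properties. The ~200-factor regime is modelled by appending named
zero-effect nuisance factors.

Missingness is missing-at-random conditional on grade only: grade-1
records complete; RA missingness ramps linearly to `missing_rate_max`
(default 0.40) at grade 6; other time-varying factors use a flat rate on
grades 2–6 scaled so the per-factor mean equals `missing_rate_mean`
(default 0.15); static registration attributes are never missing.

What passing tests on these cohorts do **not** show: robustness to
informative (not-at-random) missingness, to non-linear or interacting
factor effects, to measurement drift between schools, or to the real
cohort's unpublished factor marginals. The generator reproduces shape and
correlation structure, not the real data.

## Screening

The univariate statistic is the Pearson correlation (point-biserial
against the binary outcome) with the exact t-based two-sided p-value;
zero-variance factors report r = 0, p = 1 rather than erroring. Selection
uses strict `p < α`. The stage-2 model is OLS of the outcome on all
survivors jointly (a linear probability model when the outcome is binary),
with collinear columns dropped by incremental rank before fitting and
p-values on n − k − 1 degrees of freedom. Screening operates on
student-level reductions (the same grade-1–5 rules as the prediction
features), tolerating missing cells by observed-mean rescaling, and runs
on the students whose grade-6 refraction is observed — the outcome cannot
be read off imputed values without circularity. The dependent variable
defaults to the binary grade-6 label and is configurable to the numeric
grade-6 refraction.

## Imputation

The boosted-tree learner is intentionally written from first principles
(squared-error loss, so the initial learner is the target mean, residuals
are plain differences, and leaf values are residual means; greedy
variance-reduction splits with midpoint thresholds, ties broken towards
the lowest feature index and threshold for determinism). It reproduces an
independent library implementation to machine precision on generic data,
which the test suite checks. Defaults: 100 rounds, shrinkage 0.1, depth 3,
minimum 5 samples per leaf — all configurable.

Predictors for a missing cell at grade g: the grade itself, the always-
observed grade-1 refraction, the nearest earlier observed refraction with
its grade gap, and the student's observed-mean value of each selected
factor. Training rows are the observed RA cells at grades ≥ 2 of the same
incomplete table, so the gap distribution at train time matches fill time.

The fitting goodness is the spread ratio `Σ(f(xᵢ) − x̄)² / Σ(xᵢ − x̄)²`
about the mean of the *true* held-out values — deliberately not
`1 − SSE/SST`. It can exceed 1 for over-dispersed predictions, which is
logged rather than clipped. The error tolerance y defaults to 0.5 D (half
a diopter is the clinically meaningful refraction error) and is always
reported next to results. The error rate counts strict `|error| < y` as a
hit. A zero error rate scores REP = +∞ (unbeatable), and REP ties break
towards the larger train share, which uses more of the data. Train/test
splits at each p use one seeded permutation; proportions whose train or
test side would undercut the minimum sizes are skipped with a warning.
Model validation uses held-out complete records only; one fill pass,
no multiple imputation, no chaining of imputed values into predictors.

## Transformation

Annual progression averages consecutive-grade differences (next − previous,
so negative = myopic progression; telescopes to `(RA₅ − RA₁)/4` when
complete; direction configurable). Sums and means over grades 1–5 are
strict about completeness at this stage — after imputation, missing cells
in selected factors are a contract violation, though the pipeline-level
entry point tolerates residual non-RA gaps via observed-mean rescaling and
drops (with a log entry) students whose reduction is still undefined.
Normalization is min-max to [0, 1] with statistics learned on training
rows only; a degenerate feature (min = max) maps to 0. Grade-6 values never
enter any feature; they exist only in the label.

## Modeling and evaluation

The predictor is a linear-kernel soft-margin SVM with C = 1.0 (the library
default, kept deliberately — no hyper-parameter search), emitting
probabilities via Platt-type sigmoid calibration of the decision values; a
raw-margin variant can be had by thresholding the decision function at 0.
Labels use strict `probability > threshold`, so a probability exactly at
the threshold is negative. Metrics with empty denominators report 0 with a
warning flag instead of crashing. ROC is a threshold sweep over unique
scores with simultaneous steps on ties; AUC is trapezoidal and equals the
normalized Mann–Whitney U statistic, which the tests verify against an
independent rank-sum computation. Evaluation combines a stratified 80/20
holdout with a separate seeded stratified 10-fold CV. Baselines (logistic
regression, Gaussian naive Bayes, KNN, random forest, and a single-hidden-
layer (16-unit) back-propagation network) run under the identical harness
with library-default hyper-parameters.

The default pipeline order is screen → impute → transform → model on the
full table, mirroring the procedure the method was published with; this
leaks information across the later cross-validation folds. The
`nested=True` option repeats screening and imputation inside every fold's
training part and is the leakage-free estimate; both are first-class.

## Seeds and determinism

A single master seed derives one seed per stage by hashing the stage name
(sha256, reduced below 2³¹), so identical configurations reproduce
bit-identical cohorts, splits, models and manifests, while stages remain
independently re-runnable.

## Problem sizes in the validation suite

The property checks run at the cohort scale the method is described at
(n ≈ 3000): 200 replicates for null screening calibration, 50 replicated
cohorts for two-stage selection power, one masked cohort for imputation
recovery against a per-grade mean baseline, and one planted plus one null
cohort for the end-to-end separation property. Unit tests use cohorts of
a few hundred students.

## Known limitations

* The spread-ratio fitting goodness is not bounded above by 1 and rewards
  prediction dispersion as such; it is implemented as defined because the
  REP selection rule is the object under study, not because it is a
  recommended goodness measure.
* The linear probability model in stage 2 inherits the usual LPM caveats
  (heteroscedastic errors, fitted values outside [0, 1]); no
  multiple-testing correction is applied, matching the published flow.
* Single deterministic imputation understates downstream uncertainty.
* The synthetic null calibration covers the generator's Gaussian latent
  world; heavy-tailed or discretization-skewed real factors may calibrate
  differently.
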