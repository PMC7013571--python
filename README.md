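# myoscreen

Risk prediction for adolescent myopia from longitudinal primary-school
cohorts (grades 1–6): which measured and behavioural factors matter, how to
repair the heavily missing diopter records that such screening programmes
produce, and how well a linear support-vector machine can predict who will
be myopic by grade 6 from the grade 1–5 history.

The package is aimed at biostatisticians and epidemiologists working with
school-screening refraction data. The original cohort it models (3112
students, 57.8 % male, ~200 candidate factors, per-factor missingness
around 15 % and up to 40 % for grade-6 refraction) was never deposited, so
a first-class synthetic-cohort generator reproduces its documented shape
and statistical structure, and every stage of the analysis is exercised and
validated on that synthetic substrate.

## The method

Let `RA_ig` denote the spherical-equivalent refraction (diopters, negative
= myopic) of student *i* at grade *g*, and let a student be *myopic* when
`RA_i6 ≤ −0.5 D`.

1. **Two-stage factor screening.** For every candidate factor, compute the
   Pearson (point-biserial) correlation *r* with the outcome and its
   two-sided p-value from `t = r·√((n−2)/(1−r²))`; keep factors with
   `p < α` (α = 0.05). Fit one joint OLS regression of the outcome on all
   survivors and keep the factors whose coefficients stay significant; the
   diopter history `RA` is forced into the final subset.

2. **GBRT imputation with REP selection.** Missing `RA` cells are filled by
   a gradient-boosted regression-tree ensemble written from first
   principles: `f₀ = ȳ`, then `M` rounds of depth-bounded CART trees fitted
   to residuals with leaf values equal to the mean residual, combined as
   `f_M(x) = f₀ + ν·Σ_m Σ_j c_mj·I(x ∈ R_mj)`. The train share *p* of the
   observed cells is swept over 0.1…0.9 and each candidate model is scored
   on its test split with

       REP = R² / r,   R² = Σ(f(xᵢ) − x̄)² / Σ(xᵢ − x̄)²,

   where `x̄` is the mean of the held-out true values and *r* is the
   fraction of predictions missing the truth by at least the tolerance
   *y* = 0.5 D. The REP-maximizing *p* wins and its model fills the gaps.

3. **Factor-type transformation.** Each factor collapses to one value per
   student over grades 1–5: mean annual progression for `RA`
   (`(RA₅ − RA₁)/4` when complete), sums for behaviour frequencies, means
   for continuous ocular measurements, raw values for static attributes;
   then min-max normalization with train-only statistics.

4. **Prediction.** A linear-kernel soft-margin SVM (C = 1.0) with
   Platt-calibrated probabilities, thresholded at 0.5 (strictly greater),
   evaluated by stratified 80/20 holdout, 10-fold cross-validation,
   ROC/AUC, and compared against logistic regression, naive Bayes, KNN,
   random forest and a small back-propagation network.

## Worked example

```python
import myoscreen as ms

cfg = ms.PipelineConfig(seed=1)
cfg.cohort.effect_sizes = ms.strong_effect_sizes()  # planted-signal cohort
result = ms.run_pipeline(cfg)
print(ms.report(result))
```

The same flow is broken into narrative steps under `analysis/`
(`01_simulate_cohort.py` … `05_evaluate_models.py`), which write their
tables under `results/`. On the planted-signal cohort (n = 3112, seed 1)
they print:

```
final subset (15): DAI, GENDER, JTR, YTR, JG, YW, AL, K1, K2, PULSE, COLA, REDM, WHIM, EGG, RA
planted factors recovered: 14/14        spurious selections: none

chosen train share p = 0.7              (REP sweep over 0.1..0.9, y = 0.5 D)
held-out error rate at 0.5 D: GBRT fill 0.212 vs per-grade mean baseline 0.702

linear SVM (C = 1.0):  accuracy 0.894   precision 0.887   sensitivity 0.881
                       specificity 0.905   f1 0.884   AUC 0.960   10-fold CV 0.901
```

Reading this: both screening stages recover exactly the fourteen factors
with planted effects (plus the forced diopter history) and nothing else;
the boosted-tree fill gets ~79 % of hidden diopter values within half a
diopter where mean imputation manages ~30 %; and the SVM separates the
planted cohort with AUC 0.96. On a cohort generated with *no* planted
effects the same pipeline scores AUC ≈ 0.5, as it should.

A command-line interface mirrors the stages:

```sh
myoscreen simulate --n 3112 --seed 1 --out cohort.csv --metadata-out meta.csv
myoscreen screen   --cohort cohort.csv --metadata meta.csv --alpha 0.05 --force RA
myoscreen impute   --cohort cohort.csv --metadata meta.csv --tolerance 0.5 --out filled.csv
myoscreen run      --seed 1 --outdir runs/demo
```

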