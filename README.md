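# rpscore

Derivation and evaluation of blood-based response-prediction scores for
preoperative chemoradiotherapy (CRT) in locally advanced rectal cancer.

## The problem

Long-course CRT before total mesorectal excision is standard care for
locally advanced rectal cancer, but pathologic response varies widely:
some patients achieve a complete response while up to a third barely
respond.  A reliable early-treatment predictor would let clinicians
decide whether to continue or change course one to two weeks into
therapy.  Routine laboratory values are attractive inputs: a complete
blood count with differential drawn early during CRT reflects the
treatment-induced changes in circulating immune cells, which track the
tumor's response.

This package implements the full workflow for deriving a linear
**Response Prediction Score (RPS)** from such data:

1. **Representative splitting.**  Cohorts are partitioned 70/15/15 into
   training/tuning/validation sets with the Kennard–Stone (KS) max–min
   algorithm, mutated à la Morais–Lima–Martin (MLM): 10% of the
   KS-chosen training samples are swapped at random with held-out
   samples.
2. **Repeated benchmarking.**  Six model families (logistic, ridge and
   lasso regression, gradient boosting, random forest, a two-layer
   neural network) × five feature sets (tumor-related clinical only,
   clinical only, clinical + pre-CRT, clinical + early-CRT, clinical +
   both panels) are fitted over N repeated splits with univariate
   feature selection (Mann–Whitney U / chi-squared, P < 0.1) and
   tuning-set hyperparameter search.
3. **Generalized importance.**  For the winning linear family, the
   per-repeat coefficients β_ki (0 when a feature was not selected) are
   averaged into a generalized importance
   β_k = (1/N) Σ_i β_ki, and the score size K_o is chosen from the
   significance curve of top-K candidate scores.
4. **Score evaluation.**  The resulting weighted sum is compared against
   single blood features and the systemic inflammatory/nutritional
   indicators NLR, PLR, LMR and PNI by AUROC, and patients are
   stratified into score quartiles to read off response and downstaging
   rates.

The published five-term score ships as a constant
(`rpscore.PUBLISHED_RPS`; higher = less likely to respond):

```
RPS = 0.000559·monocyte_early + 0.026172·distance_from_anal_verge
    + 0.001021·platelet_early + 0.000049·neutrophil_early
    − 0.000433·eosinophil_early
```

with counts in cells/µL, platelets in 10³/µL and distance in cm.

Because no patient-level data are publicly deposited, the package
includes a first-class synthetic cohort generator
(`rpscore.generate_cohort`) that reproduces the statistical structure the
analysis assumes — ~272 patients, ~43% good responders (tumor regression
grade 0–1), log-normal blood counts with treatment-induced decline, and
planted directional effects on the early-treatment monocyte, platelet,
neutrophil and eosinophil counts and on tumor distance — so every stage
is exercisable and testable end to end.

## Worked example

```python
from rpscore import SynthConfig, generate_cohort, ResponseScoreModel

cohort = generate_cohort(SynthConfig(seed=11)).table
results = ResponseScoreModel(cohort, n_repeats=100, seed=0).fit()
print(results.summary())
```

```
Response score derivation
============================================================
model family:    ridge    feature set: clinical_early
repeats:         100    cohort n: 272    seed: 0
validation AUROC 0.8018 +/- 0.0500    AUPRC 0.8727 +/- 0.0439
score size K_o:  10    min Mann-Whitney P: 6.796e-22

top 10 features by |standardized mean coefficient|:
feature                     beta_raw  beta_std   sel%  sign%
------------------------------------------------------------
early_monocyte              0.000480    0.0784   100%    99%
early_eosinophil           -0.001264   -0.0777   100%   100%
early_neutrophil            0.000047    0.0514   100%    99%
distance_anal_verge         0.017248    0.0503   100%   100%
early_PLT                   0.000655    0.0424   100%   100%
...
```

The five planted-effect features head the importance ranking with the
planted signs, and the per-repeat coefficient signs are almost perfectly
consistent (`sign%`), mirroring how a stable linear score should emerge
from repeated representative splits.  Quartile stratification of the
derived score shows the expected monotone gradient in good-response
rate:

```python
report = results.stratify()
print(report.rates.round(3))
```

```
group  good_response_rate  overall_downstaging_rate  t_downstaging_rate  n_downstaging_rate
   Q1               0.794                     0.765               0.868               0.647
   Q2               0.500                     0.485               0.632               0.632
   Q3               0.162                     0.250               0.412               0.515
   Q4               0.103                     0.191               0.353               0.544
```

and `results.compare()` confirms the multivariable score outranks every
single blood feature and every inflammatory indicator on this cohort
(score AUROC 0.846 vs 0.742 for the best single feature).

A command-line interface mirrors the library
(`rpscore synth | split | bench | derive-score | score | compare |
stratify | run-all`); `rpscore run-all --seed 1 --outdir results/` writes
the cohort, benchmark table, importance table, score JSON, comparison,
stratification, significance curve and a reproducibility manifest.

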