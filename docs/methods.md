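# Methods

This note records the models, conventions and design choices behind
`rpscore`, in the spirit of a statistical package's model documentation.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Cohort model and feature dictionary

A cohort is a flat per-patient table.  Clinical features: distance of
the tumor from the anal verge (cm), serum CEA (ng/mL), tumor grade
(ordinal 1–3), age, sex, clinical T (1–4) and N (0–2) stage.  Blood
panels: a 17-feature complete blood count with differential measured
both before CRT (`pre_`) and 1–2 weeks after its start (`early_`), and a
12-feature chemistry panel measured pre-treatment only — consequently
the prognostic nutritional index (PNI), which needs albumin, exists only
for the pre-treatment epoch.  Outcomes: AJCC tumor regression grade
(TRG 0–3) and pathologic ypT/ypN stage.

Units are fixed so the published score weights are unit-consistent:
cell counts in cells/µL (= /mm³), platelets in 10³/µL, albumin in g/dL,
distance in cm.  With adult reference-range inputs these units put the
five-term score in roughly the 0.3–1.0 range, the same order as its
published quartile cut-offs.  The shipped `schema.yaml` is the
authoritative column dictionary.

Derived indicators: NLR = neutrophil/lymphocyte,
PLR = platelet/lymphocyte (platelets converted to /µL first),
LMR = lymphocyte/monocyte, PNI = 10·albumin (g/dL) + 0.005·lymphocytes
(/mm³).  Indicators are *comparison baselines*, not model inputs.

The binary response label takes the **poor responder (TRG 2–3) as the
positive class**, so every risk score is oriented "higher = less likely
to respond".  This orientation is inferred from the signs of the
published score (positive monocyte/neutrophil weights, and those counts
are reported lower in complete responders) and from the negated
reporting of LMR among the baselines; it is stated here prominently
because it fixes the sign of every coefficient in the package.

"Clinical only" membership beyond the tumor-related trio
(distance, CEA, grade) is not fully enumerable from the source analysis;
the package defines it as trio + age + sex + clinical T + clinical N.

Overall downstaging is ypT0–2 N0 (M0 by the study population);
T-/N-downstaging compare pathologic with clinical stage.

## 2. Synthetic cohort generator

The generator emulates the *statistical structure* of the study cohort,
not its empirical distributions (which are unpublished):

* n = 272 patients by default; good-responder prevalence 0.43.
* Pre-treatment values are log-normal around adult reference medians
  with feature-specific log-dispersions; the five leukocyte differential
  counts share a per-patient "inflammation" factor (log-sd 0.08) and sum
  to the white-cell count, giving a simple shared-factor correlation
  structure.  Richer inter-analyte correlation (e.g. plateletcrit as
  platelet×volume) is deliberately out of scope.
* Early-treatment counts are the pre-treatment counts times a decline
  factor (cytopenia during CRT: lymphocytes ×0.35, neutrophils ×0.60,
  platelets ×0.80, red-cell indices nearly stable) times log-normal
  visit noise (log-sd 0.12).
* TRG is sampled from an ordinal logistic link on a latent standard
  normal response propensity; the good/poor cut-point is solved
  numerically (Gauss–Hermite quadrature + root finding) so the marginal
  good-responder fraction equals the configured prevalence, and the
  outer cut-points sit at fixed offsets giving plausible complete
  (TRG 0) and absent (TRG 3) response rates.  ypT and ypN are drawn
  from TRG-conditional tables; TRG 0 forces ypT0/ypN0, so a complete
  response always implies overall downstaging, and good responders
  downstage more often by construction.
* Planted effects: poor responders receive signed shifts on
  early-treatment monocyte (+0.8), platelet (+0.6), neutrophil (+0.6)
  and eosinophil (−0.5) counts and on distance from the anal verge
  (+0.5).  Blood-count shifts are applied on the log scale and
  calibrated to each feature's *total* log-dispersion (base + shared
  factor + visit noise), so the nominal effect is the realized
  standardized shift on that scale.  On the natural scale the shift is
  slightly attenuated for high-dispersion features (log-normal tails);
  rank-based tests are unaffected.  Pre-treatment features carry no
  planted effect, so models restricted to them predict near chance.
  The default magnitudes are the package's one-time choice of
  clinically plausible moderate effects; they are fully overridable
  per feature via `SynthConfig.effect_sizes`.
* Missingness is MCAR on the blood panels only, default rate 0.

What passing tests on this generator do **not** show: performance on
real patients.  The generator has idealized distributions, a single
shared factor, no batch or era effects, and exactly the planted signal;
recovery results are statements about the *procedure* (it finds what was
planted at realistic n and effect sizes), not about clinical validity.

## 3. Splitting

Standardization uses the population (ddof = 0) convention; zero-variance
columns keep scale 1 and are flagged.  Kennard–Stone seeds with the two
mutually farthest samples (classic form; a "max mean distance"
single-seed initialization is available) and then greedily adds the row
maximizing the minimum Euclidean distance to the selected set, ties
broken toward the lowest row index, making the algorithm fully
deterministic.

The MLM split KS-selects round(0.70·n) training rows, then swaps
round(0.10·|train|) uniformly chosen training rows 1-for-1 with
uniformly chosen held-out rows (sizes are exactly preserved).  The
source analysis does not state how the 30% remainder becomes tuning vs
validation, nor whether mutation happened before or after that carve;
the package mutates first and then divides the pool by a second KS pass
(tuning = KS-selected rows), so both held-out sets are representative;
a random division is available via `holdout_method="random"`.
Categorical features enter the distance as standardized integer codes —
a documented limitation.

## 4. Benchmark

Per repeat: a fresh MLM split of the full feature matrix (shared across
feature sets so all cells see the same partition); univariate selection
on training rows only (Mann–Whitney U for continuous, Pearson
chi-squared for categorical features; P < 0.1), skipped for the two
small clinical-only sets and for lasso (its penalty selects) and the
neural network (it extracts features); standardization with training
center/scale (missing values imputed at the training mean); grid search
scored by tuning-set AUROC with ties resolved to the less complex
configuration (grids are ordered simple → complex; for penalized linear
models, stronger penalty first).

Model families map to scikit-learn estimators: unpenalized logistic
regression; ridge and lasso as least-squares fits to the 0/1
poor-responder label (their continuous prediction is the risk score,
which matches the published score's 0.3–1.0 scale; a log-odds scale
would not); gradient boosting; random forest; and a two-layer neural
network read as one hidden layer (8/16/32 units) + logistic output.
The hyperparameter grids replace unpublished search spaces: ridge/lasso
penalty on a 7-point log grid [1e−3, 1e3]; boosting {50, 200 trees} ×
{depth 2, 3} × {learning rate 0.05, 0.1}; forest {200, 500 trees} ×
{depth 3, unlimited}; the network uses early stopping on an internal
validation split (a scikit-learn API constraint; the tuning set still
chooses among hidden sizes).

Linear coefficients are back-transformed to raw units
(β_raw = β_std / scale) and stored per repeat with 0 for unselected
features, so across-repeat averages encode both magnitude and selection
frequency.  The "optimal cut-point" is Youden's J on the validation ROC
(the source analysis leaves it undefined).  No class-imbalance handling
beyond what estimators do natively — cohorts here are near-balanced.

Calibration diagnostic: the permutation-null mode
(`BenchConfig.permute_labels`) shuffles the label vector freshly per
repeat, making repeats independent draws from the
"labels independent of features" null; every cell's mean validation
AUROC then concentrates near 0.5.  Note that a *single* null cohort (or
a single label permutation) does not behave this way: all repeats then
resplit one fixed cohort, whose idiosyncratic chance correlations are
shared between training and validation rows, so per-cell means land
anywhere in roughly 0.4–0.6.  This is a property of repeated resplitting
itself, worth keeping in mind when reading small-cohort benchmark
tables.

## 5. Score derivation

Generalized importance averages the per-repeat coefficients featurewise
(0-imputed for unselected repeats).  **Ranking is by the magnitude of
the standardized-scale mean coefficient**, which is unit-free and
therefore comparable across counts, percentages and centimetres; the
reported score weights stay on the raw scale so the score is a plain
weighted sum of laboratory values.  (Raw-scale magnitudes would rank
features by their units: the published score's own stated importance
order is inconsistent with raw-scale ranking, which corroborates this
reading.)  Sign consistency is the fraction of selecting repeats whose
coefficient sign matches the sign of the mean (reference pinned to + on
an exact-zero mean; undefined when never selected).

Score size: for K = 1..K_max (default 10) the top-K raw-weight score is
evaluated on all patients (cohort-median imputation for gaps) and tested
against the label with a two-sided Mann–Whitney U; K_o is the argmin of
the P curve, smallest K on ties, and degenerate all-equal scores score
P = 1.  The curve is returned for plotting.  Caveat: these P-values are
in-sample — the candidate score was built from coefficients fitted on
the same cohort — so they are a model-selection device, not calibrated
null tests; on label-independent data the minimum of the curve is still
usually small.

Predictor comparison computes the AUROC of every single blood feature,
the four pre-treatment and three early-treatment indicators, and the
score; predictors with AUROC < 0.5 are negated and prefixed "−"
(low lymphocyte-to-monocyte ratio predicts poor response).  Quartile
stratification uses linear-interpolation quantiles with right-closed
groups (−∞,Q1], (Q1,median], (median,Q3], (Q3,∞); heavy ties that empty
a group produce a warning, not an error.  No monotonicity is assumed for
T-downstaging in reports.

## 6. Evaluation metrics

All metrics are pinned conventions, implemented in-package and
cross-checked against independent references in the test suite:

* AUROC = tie-adjusted pairwise concordance (midranks), identical to
  trapezoidal ROC area over distinct thresholds.
* AUPRC = step-interpolated (right-continuous) precision–recall area —
  the average-precision convention, avoiding linear interpolation's
  optimistic bias.
* Mann–Whitney U: U of the first sample; two-sided P from the normal
  approximation with tie-corrected variance and 0.5 continuity
  correction (no exact small-sample path — adequate at cohort scale,
  and within 1e−6 of reference implementations at n ≥ 20).
* Chi-squared: Pearson statistic, no continuity correction.
* Classification at threshold t calls score ≥ t positive; Youden ties
  resolve to the lower threshold.

## 7. Reproducibility and problem sizes

A single master seed fans out via `numpy` seed sequences to per-repeat
split seeds, estimator seeds and permutation seeds, so every artifact is
a pure function of (config, seed); the pipeline writes a manifest with a
hash of the analysis-relevant config.  Default problem sizes are chosen
for interactive use: 100 repeats with the linear families (the
derivation cell), full 6-family benchmarks behind explicit
configuration; the test suite exercises calibration at 100 repeats ×
2 linear families × 5 feature sets and recovery over 5 independent
master seeds at 100 repeats each.

## 8. Known limitations

* Generator realism is deliberately limited (Section 2).
* KS tie-breaking by row index makes selection order, not just the
  selected set, the documented contract; permutation equivariance holds
  set-wise for distinct distances.
* Importance is defined for coefficient (linear) models only; tree and
  network importances are out of scope.
* No confidence intervals on AUROC and no multiple-testing correction —
  matching the workflow this package reimplements.
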