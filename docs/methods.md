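# Methods

## Problem setting

`clinaug` targets binary classification on small clinical tables: n between
roughly 70 and 2000 patients, a handful to a few dozen numeric features, and
a case (positive-class) fraction between ~2% and ~37%. The package provides
the three oversampling algorithms most used in this setting (GNUS, SMOTE,
ADASYN) plus plain random up-sampling, and a benchmark harness that measures
whether augmenting the minority class before model fitting improves held-out
classification.

## Data model and missing-value policy

A `LabeledTable` holds a dense numeric feature matrix and a 0/1 label vector
with class 1 the minority ("case"). If the declared positive class turns out
to be the majority, labels are flipped with a warning so oversampling always
targets class 1.

CSV loading applies a two-pass missing-value policy: first drop every
feature column whose missing fraction is at least a threshold (default 0.5),
then drop every row with any remaining missing value. Removing samples *and*
features with missing values admits several orders; column-first with a
configurable threshold is used because an any-missing column rule would
discard nearly every column of sparsely missing clinical data, whereas
column-first reproduces the kind of reduction seen in real cervical-cancer
risk data (858 → 761 complete rows with 7 features retained). The policy is
idempotent, and drop counts are reported. Non-numeric feature columns are a
fatal error unless explicitly dropped; imputation is out of scope.

Manifest summaries (mean, median, quartiles of sample sizes and case
percentages) use the type-7 linear-interpolation quantile convention
(h = (n−1)q, interpolate between bracketing order statistics) and round case
percentages to two decimals before summarising, matching the precision at
which such tables are printed. One published summary of the ten-dataset
collection states a median imbalance of 17.7%; the median of the ten printed
percentages is 17.87%, and the computed value is what `summarize_manifests`
reports.

## Oversampling algorithms

All methods append synthetic minority rows after the originals, which are
preserved bit-for-bit and in order. The default synthesis target is exactly
`n_controls − n_cases` rows, i.e. a balanced table — the size is not fixed
by convention in the literature, and class balance is the standard choice
that also makes the methods directly comparable. Per-method notes:

* **random_upsample** draws sources uniformly with replacement; a balanced
  input returns unchanged with an empty synthetic set.
* **gnus** adds independent per-feature noise N(scale·x̄ᵢ, scale·sdᵢ) to
  each duplicated row, with x̄ᵢ and sdᵢ (sample sd, n−1 denominator)
  computed over the minority rows of the *input* table — the rows the noise
  is applied to. `scale` defaults to 0.001. The noise mean scale·x̄ᵢ
  introduces a small systematic shift; this is the method's published form
  and is implemented as such, with `NoiseSpec(zero_centered=True)` as an
  option that removes the shift. A singleton minority class has no sample
  sd; σᵢ is then 0 (duplication plus mean shift) with a warning.
* **smote** picks base rows by cycling a random permutation of the minority
  set, so per-row synthesis counts differ by at most one even when the
  deficit is not a multiple of n_min; the neighbour is uniform among the
  base's k nearest minority neighbours (self excluded), k shrunk to
  n_min − 1 when necessary; u ~ U[0,1] on the segment.
* **adasyn** computes rᵢ from the k nearest neighbours in the full dataset,
  normalises to weights, and integerises G·wᵢ by largest remainder so the
  total is exact (plain rounding can miss G by several units). Perfectly
  separated classes (all rᵢ = 0) fall back to uniform allocation with a
  warning. Some descriptions characterise ADASYN as "SMOTE plus noise"; the
  canonical density-adaptive algorithm (as in the R `smotefamily`
  implementation) is what is implemented here.

k-NN uses Euclidean distance on raw (unstandardised) features, mirroring the
reference implementations' defaults; distance ties break toward the lower
row index so seeded runs are platform-stable. Both interpolating methods
record (base, neighbour, u) provenance for every synthetic row, which is
what the geometric tests verify against.

## Metrics

ROC AUC is the rank-based (Mann–Whitney) statistic with midrank tie
handling. PR AUC integrates the precision–recall staircase by the trapezoid
rule on recall, with the precision at recall 0 carried from the first
attainable operating point rather than pinned at 1 (integration conventions
differ between packages; the hand-enumerated staircase is the correctness
anchor in the tests). F1 and MCC are computed from the confusion table at a
0.5 threshold on predicted case probability — the scalar-per-run convention;
the threshold is configurable. Degenerate denominators: F1 and MCC return 0;
single-class test partitions make the AUCs undefined, and the cell is
recorded as missing rather than imputed.

## Benchmark harness

`run_mccv` repeats a stratified random 80/20 split (test fraction
configurable; per class the rounded share, clamped so both partitions keep
at least one sample of each class). Within a repeat, every method and model
sees the identical split; only the training partition is augmented, so
test-set leakage into the synthetic pool is impossible by construction and
is additionally asserted by row-identity checks in the test suite. Missing
cells (fit failures, degenerate partitions) are logged and dropped per
comparison.

Classifiers delegate to scikit-learn behind a two-method contract
(`fit`, `predict_case_probability`): unpenalised logistic regression (logit
link), random forest with 500 trees and √p candidate features per split, and
C-SVMs (linear / RBF / degree-3 polynomial, bandwidth by the 'scale'
heuristic, Platt-scaled probabilities). Defaults mirror the standard R
implementations these models are usually run with; no hyperparameter tuning.

All randomness derives from one master seed through named
`SeedSequence(entropy, spawn_key)` streams per (repeat, method, model), so
any single cell can be reproduced in isolation.

`compare_methods` runs equal-variance Student's t-tests of each method's
per-repeat metric vector against the null model's (the published protocol
names Student's test; a paired option exists since splits are shared, and
Welch could be argued for but is not the printed choice). The BH step-up
adjustment spans the whole family within one dataset — all models × metrics
× methods — the most conservative reading of "corrected for multiple
testing". Zero-variance edge cases: identical constant vectors give t = 0,
p = 1; constant but unequal vectors give the p = 0 boundary and are flagged
in the log.

## Synthetic data generator

Controls are drawn from N(0, Σ) and cases from N(δ·e, Σ) with Σ the AR(1)
correlation matrix ρ^|i−j| and e the indicator of the first `n_informative`
features (default ⌈p/2⌉). A Gaussian class-conditional model is appropriate
because the emulated benchmark datasets are all numeric tabular; the
generator does not emulate heavy tails, mixed types, measurement units, or
missingness, so passing benchmarks here demonstrate protocol correctness and
qualitative behaviour, not performance on any real cohort. The case count is
fixed by rounding (`round(case_fraction · n)`), not by Bernoulli sampling,
so augmenter count arithmetic is exact. `benchmark_presets()` reproduces the
(n, case count, feature count) triples of the ten-dataset clinical
collection, with δ = 1 and ρ = 0.3 as mid-range difficulty defaults; the
HCV entry uses 12 features (the standard UCI HCV laboratory panel), the one
count not in the collection's running text.

## Calibration and the permutation null

A single fixed label permutation of one finite dataset is *not* an unbiased
null for repeated splitting: conditional on the dataset's realised
feature–label correlation, the training-partition estimate and the
test-partition effect are anti-correlated (their weighted sum is pinned to
the fixed total), which biases held-out AUC below 0.5 — empirically to
~0.36 at n = 150, p = 4. `permutation_calibration` therefore redraws the
permutation every repeat, which cancels the bias exactly; its mean AUC is
the quantity expected to sit in [0.45, 0.55].

## Problem sizes used in the checked experiments

The package's own acceptance checks run at: descriptive statistics on the
ten manifests; oracle equivalence at n ≤ 500; geometry on 50 random
datasets; GNUS moments from 10,000 draws; anti-leakage over a 100-repeat
MCCV of the 72-sample preset; calibration at 200 (permuted) and 100
(separable) repeats; and the directional experiment at n = 942, 10.3%
cases, δ = 1, 200 repeats with a 250-tree forest — forest size is the one
place the checks depart from the 500-tree default, a problem-size choice
that leaves the measured direction unchanged (at 500 trees and 25 repeats:
null F1 0.506 vs GNUS 0.544, SMOTE 0.576, ADASYN 0.579). The acceptance
script runs the directional experiment at 100 repeats.

## Known limitations

* Only numeric features; no SMOTE-NC-style categorical handling, no
  borderline/SVM-SMOTE variants, no under-sampling (inappropriate when the
  data are already small).
* F1/MCC at a fixed 0.5 threshold; threshold optimisation is out of scope.
* The generator's Gaussian world cannot certify behaviour on real clinical
  cohorts; it certifies the algorithms and the protocol.
* Runtime comparisons between augmenters are hardware-dependent and are not
  an acceptance surface.
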