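# Methods

This note documents the models, estimators, defaults and design choices
behind `rppaclass`, and what the synthetic-data tests do and do not show
about real RPPA data.

## The classification problem

The input is a sample × protein matrix of normalized RPPA expression
values (unitless, real), one class label (tumor type) per sample. The
reference cohort shape the package targets is ten tumor types over 3467
samples and 187 proteins, with strongly unbalanced classes (the largest
class is ~6× the smallest) — the two colorectal types are merged into a
single class before analysis (`merge_classes`). The deliverable is a
small ordered protein panel plus an honest estimate of how well that
panel predicts the tumor type.

## Pipeline stages and their parameters

### Stratified split

`stratified_split(dataset, test_fraction, seed)` holds out a test
partition before anything else happens. Per-class test counts are
`round-half-down(n_c · fraction)`; if the per-class sum misses the
rounded global target, the largest classes are adjusted by one sample
each until it is exact. At a 4:1 ratio on the reference cohort's class
sizes this reproduces the published per-class train/test counts exactly
with no correction step needed (asserted in the test suite). Default
`test_fraction = 0.2`.

An existing train/test membership table can be consumed verbatim
(`apply_split`) when the data distribution already fixes the split.

### Discretization and mutual information

The MI estimator operates on discrete variables, so each feature is
binned into three levels: *low* below μ − kσ, *high* above μ + kσ, *mid*
between, with μ, σ the feature's sample mean and population SD and
k = 1 by default (`DiscretizationConfig.k_sigma`). Mean ± 1σ
three-binning is the long-standing convention for mRMR on expression
data; a constant feature (σ = 0) becomes all-mid and carries zero MI
with everything. Class labels are categorical already and are never
discretized.

MI is the plug-in (maximum-likelihood) estimator on the joint frequency
table, in nats. The log base is irrelevant to the ranking — it rescales
relevance and redundancy by the same constant. The in-package estimator
is cross-checked in the tests against `sklearn.metrics.mutual_info_score`
and against an independent hand-rolled frequency-table oracle.

### mRMR greedy ranking

Step 1 picks the feature with maximal relevance I(f, c); step m + 1
maximizes `I(f, c) − (1/m) Σ_{s∈selected} I(f, s)` over the remaining
features; the loop runs for all N features, yielding a complete ranking
with per-step objective values.

Numerical tie policy: two candidate scores closer than 1e-12 are one
mathematical value up to floating-point rounding (this occurs whenever
two features discretize to equivalent partitions) and are treated as
tied; ties go to the leftmost original column. This makes the ranking
exactly reproducible and platform-independent, and it is the same rule
the brute-force oracle in the tests applies.

### Cross-validation and the IFS curve

Folds are class-stratified and seeded: samples are shuffled within each
class, concatenated, and dealt round-robin, so fold sizes differ by at
most one and each class spreads as evenly as its size allows. Every
sample is predicted exactly once by a model that did not train on it.

Out-of-fold predictions are **pooled** into a single confusion matrix
per (prefix, classifier) and the MCC computed once on it, rather than
averaging per-fold MCCs. Pooling keeps the statistic defined when a rare
class is absent from some fold and avoids the variance of per-fold
estimates on small classes. One fold assignment is computed per IFS run
and reused across every prefix and every classifier, so curve points
differ only in the quantity of interest.

`select_optimal` implements two policies:

* `first_above(θ)` (pipeline default, θ = 0.900): the smallest prefix
  whose MCC reaches θ — a parsimony rule that yields the smallest panel
  with acceptable performance; falls back to `argmax` if the curve never
  reaches θ.
* `argmax`: the smallest prefix attaining the curve's maximum MCC — the
  literal "best-performing feature set" definition.

The two policies answer different questions: `first_above` optimizes
panel compactness, `argmax` optimizes recovery of everything that helps.
Panel-recovery assessments in the acceptance suite therefore use
`argmax`: under a parsimony rule, a panel that is *deliberately* smaller
than the planted signal set cannot and should not contain all of it.

### Classifiers

All four share one train/predict contract; class vocabulary order is the
order of first appearance in the training labels, and every tie-break
refers to that order. All are deterministic given the spec seed.

* **svm_smo** — one binary soft-margin SVM per class pair, combined by
  one-vs-one pairwise voting (vote ties to the earliest class). Features
  are standardized to training mean/SD. The binary quadratic programs
  are solved by scikit-learn's libsvm backend (an SMO-family solver);
  the standardization and the pairwise combination are owned by this
  package. Defaults: linear kernel, C = 1 — the common defaults of the
  classic toolkits for this kind of data.
* **ib1** — 1-nearest-neighbor with normalized Euclidean distance: each
  feature is min-max scaled to [0, 1] by its *training* extremes; a
  zero-range feature contributes 0 to every distance; distance ties go
  to the earliest training sample.
* **dagging** — k disjoint, class-stratified subsamples of size
  ⌊n/k⌋ (so k·n′ ≤ n; leftovers are unused), one base learner per
  subsample, majority vote. Defaults: k = 10, base = svm_smo. A subset
  that degenerates to a single class is dropped from the ensemble.
* **random_forest** — scikit-learn, 100 trees, ⌊√p⌋ features per split.

### Metrics

The multiclass MCC is implemented twice on purpose: once in closed form
from the confusion matrix and once from the one-hot indicator matrices
as `cov(X,Y)/√(cov(X,X)·cov(Y,Y))`; the test suite asserts the two
routes agree to 1e-10 on a thousand random matrices and that the
multiclass form reduces exactly to the familiar binary MCC on 2×2
tables. Whenever a denominator factor vanishes (a class never predicted
and never true, all predictions in one class, a single-class truth) the
coefficient is defined as 0, the no-information value — this keeps IFS
curves total on degenerate prefixes.

Confusion-matrix orientation is fixed: rows = true class, columns =
predicted class.

## The synthetic-data generator

`simulate.generate` emulates the *shape* of a pan-cancer RPPA cohort,
not its biology:

* class sizes default to the reference cohort's tumor-type proportions
  scaled to ≈ 500 samples (499), keeping the realistic imbalance;
* 20 *informative* features are Gaussian with unit within-class SD and
  class means at ±`effect_size`/2 on a seeded random sign grid
  (re-drawn until all class rows are distinct, so every class pair
  differs in expectation on ≥ 1 informative feature); `effect_size = 2`
  by default — a well-separated but noisy signal;
* 20 *redundant* features are jittered copies of informative sources
  (`redundancy_noise_sd = 0.2`, giving source–copy correlation > 0.9),
  emulating antibodies that track one signal;
* 147 *noise* features are standard Gaussian, independent of class,
  bringing the total to the reference 187.

What passing tests on this generator demonstrate: the ranking prefers
planted signal over noise and penalizes duplicates, the IFS curve rises
as signal accumulates, the selected panel recovers most planted
informative features, and an all-noise cohort yields CV MCC ≈ 0. What
they do not demonstrate: behavior under real RPPA antibody noise,
batch effects, inter-protein biological correlation networks, or
missing values (missing cells are rejected, not imputed — the intended
inputs are complete, pre-normalized matrices).

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full workflow on the default 499-sample
cohort with a 4:1 split, 10-fold CV, and the IFS curve traced over the
top 40 ranks — the signal-bearing rank budget (n_informative +
n_redundant); beyond it only noise columns remain by construction, the
curve is flat there, and the desk-scale run stays fast. The panel is
selected by `argmax`; the test partition is touched exactly once.

## Known limitations

* Feature ranking is performed once on the full training partition, and
  CV then evaluates prefixes of that fixed ranking — the selection is
  not nested inside the folds, so training-set CV MCCs carry some
  selection optimism. The held-out test evaluation is unaffected. This
  mirrors the classical mRMR + IFS workflow; a nested variant is out of
  scope.
* The plug-in MI estimator with mean ± 1σ binning is one of several
  defensible choices; rankings from other estimators (finer bins,
  continuous k-NN estimators) will differ in detail, so panel
  *membership* on a given real dataset is estimator-dependent even when
  panel *performance* is stable.
* The pairwise SVM combination uses hard voting, not probability-based
  coupling; with many classes and few votes, ties are resolved by
  vocabulary order.
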