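# Methods

## Problem setting

cigtml works on CIGT (Clinically Integrated Genomics and Transcriptomics)
tables: one row per patient, with a unique identifier, a binary diagnosis
(0 = control, 1 = case), optional demographic attributes (numeric or
categorical) and per-gene expression values derived from RNA-seq. The
package assumes expression has already been quantified and normalized
upstream; values are continuous and may be negative. Three questions are
answered: which features are associated with the diagnosis (selection),
how well can the diagnosis be predicted from them (classification), and
how much does the prediction machinery rely on each biomarker, and in
which polarity (I-Gene scoring).

## Input handling

Files are comma-separated UTF-8 with a header; the identifier and label
columns default to `ID` and `Type` and are overridable everywhere.
Non-numeric columns are treated as categorical demographics and encoded
as deterministic lexicographic integer codes — never one-hot — so that
each input column remains a single feature in every downstream report.
Missing values are rejected by default; an explicit opt-in performs
per-feature median imputation (with a hook for supplying train-only
medians to avoid evaluation leakage). Rows are always patients and
columns always features; no orientation guessing.

Train/test partitioning is a stratified split (default 30% held out):
class proportions in each part are within one sample of the cohort
proportion, the two parts are disjoint and exhaustive, and the partition
is a pure function of the seed.

## Feature selection

Four selectors run independently on the training split and are combined
by union (default), intersection, or at-least-k voting. Zero-variance
features are excluded with a logged warning in every selector, never an
exception; an empty combined set is an explicit error, never a silent
pass-through.

- **Point-biserial screen** — Pearson correlation r between each feature
  and the 0/1 label, tested with t = r·√((n−2)/(1−r²)) on n−2 degrees of
  freedom, two-sided.
- **Chi-square test** — each feature is dichotomized at its pooled mean
  (a monotone, label-free cut) and the 2 × 2 low/high × class count table
  is tested with the classic Pearson chi-square statistic, no continuity
  correction, df = n_classes − 1. Counts are used because the chi-square
  null model is a count model: scoring raw continuous totals makes the
  test arbitrarily conservative (we measured a rejection rate of 0.000 at
  α = 0.05 on scaled Gaussian nulls). The mean cut is preferred to the
  median cut because the median pins the table margin at exactly n/2 and
  the resulting fixed-margin discreteness inflates the rejection rate
  (measured 0.0645 at n = 100/100 versus 0.0565 for the mean cut against
  a nominal 0.05, over 20 000 simulated null features).
- **ANOVA** — one-way F between case and control groups; with two groups
  F equals the squared pooled-variance t statistic, an identity the test
  suite asserts.
- **RFE** — recursive feature elimination, removing one feature per
  iteration under a 100-tree random-forest importance backend, keeping
  10% of features by default (at least one); deterministic given its
  seed.

Default α = 0.05 with no multiple-testing correction, because selection
here is a screening step feeding a predictive model rather than an
inferential endpoint; a Benjamini–Hochberg FDR flag is available.
Demographics are eligible for selection like any feature, with a
force-include option. Union is the default combination because the
intersection of four heterogeneous selectors is frequently empty on
small cohorts.

## Classification

Five probabilistic base learners are fitted on a shared standardized
(train-fitted z-score) matrix of the selected features: random forest
(100 trees), RBF-kernel SVM with calibrated probabilities, XGBoost with
library defaults, k-NN (k = 5), and an MLP with one hidden layer of 100
units and at most 500 iterations. Trees are scale-invariant, so sharing
the standardized matrix is harmless for them and necessary for the
scale-sensitive members. No hyperparameter search is performed; all
values are exposed in `EnsembleConfig`.

Two voters aggregate the enabled members: the soft voter averages case
probabilities and calls a case when the mean is ≥ 0.5 (a 0.5 tie is a
case, by convention); the hard voter takes the majority label and
resolves exact ties — possible only with an even member count — to
control, logging the event. The asymmetry is deliberate and documented:
the soft tie sits exactly at the decision boundary where either call is
defensible, while a hard tie means the ensemble genuinely disagrees and
the conservative call is no diagnosis. Metrics reported per classifier
(including both voters): accuracy, F1 and ROC-AUC; on a single-class
evaluation set AUC is NaN with a warning.

## Attributions

No external explainer is used: the package computes interventional
Shapley values directly. For sample x and coalition S, the value
function is v(S) = E_b[f(x_S, b_{∼S})] over a background matrix b of
training rows (subsampled, seeded, to at most 100 rows by default — 50
in the benchmark studies), with f the member's case-probability. Two
evaluation paths:

- **Exact enumeration** over all 2^d coalitions, used automatically up
  to d = 8 selected features.
- **Permutation sampling** (default 20 orderings, 10 in the benchmark
  studies; seeded) beyond that. Marginal contributions telescope within
  each ordering, so local accuracy — baseline + Σ_j φ_j = f(x) — is
  exact for both paths at any number of orderings; sampling noise
  affects only how credit is split among features.

The test suite checks both paths against a brute-force oracle that
averages marginal contributions over every feature ordering, written
independently of the implementation.

Attributions explain the case probability, not the decision label, so
signs carry magnitude information: positive values push toward a case
call. Voters are excluded from attribution: majority voting has no
probabilistic output of its own to explain.

## I-Gene scoring

For each non-degenerate base classifier c and feature f:

- importance share s_{c,f} = mean_samples |φ_{c,s,f}| normalized so that
  Σ_f s_{c,f} = 1;
- concentration HHI_c = Σ_f s_{c,f}² ∈ [1/n, 1] (unit-interval
  convention, not the ×10 000 economics scale);
- classifier weight w_c = HHI_c / Σ_c HHI_c — proportional-to-HHI, the
  simplest monotone rule: classifiers whose predictions rest on few
  biomarkers weigh more;
- raw I-Gene score raw_f = Σ_c w_c · s_{c,f}. Because weights and each
  share vector sum to one, Σ_f raw_f = 1 identically (asserted in
  tests); the displayed score rescales raw by its maximum onto 0–100.

A classifier whose attributions are all zero (e.g. a constant model) is
flagged degenerate and excluded from both weighting and scoring, with a
warning; if every classifier degenerates, scoring raises. HHI is
computed over the full selected-feature set.

**Directionality.** Default rule: for each feature, the Pearson
correlation between feature values and per-sample attributions, averaged
across classifiers with the HHI weights. A weighted correlation above
+τ labels the feature overexpressed (high values push toward a case
call), below −τ underexpressed, otherwise neutral; τ = 0.1 keeps
noise-level features from receiving a direction. An alternative reading —
comparing case and control mean feature values among positively
attributed samples, standardized by the feature SD — is implemented as
`positive_mean_compare` and exposed via a flag; the correlation rule is
the default because it is symmetric in both polarities and needs no
labels at scoring time.

## Synthetic cohorts

The generator draws expression as Gaussian noise, N(8, 1) by default,
reflecting processed log-scale expression rather than raw counts;
informative genes receive a mean shift of ±d·σ in cases, with polarity
alternating up/down by gene index so both directions are exercised in a
single cohort. Optional demographic columns (numeric or categorical) are
drawn independently of the label. A single seed drives one named RNG
stream; identical configuration gives bit-identical cohorts.

The benchmark study conditions, used as generator defaults and
throughout the tests, are a balanced 100/100 cohort of 50 genes with 5
informative at d = 2 — strong signal a working pipeline must recover
essentially perfectly — plus a 200/200 variant for directionality and
1000-gene null cohorts for calibration. What passing these tests shows:
the statistical machinery is calibrated, the plumbing is leak-free, and
planted signal of textbook strength is found, ranked on top and
polarity-labelled correctly. What it does not show: behavior under
realistic RNA-seq complications — overdispersed counts, library-size and
batch effects, correlated co-expression modules, label noise, class
imbalance — none of which the generator emulates.

## Determinism and numerical choices

One pipeline-level seed fans out to named substreams (split, RFE,
ensemble, explainer, plot jitter) via `SeedSequence.spawn`, so every
stochastic stage is reproducible and two runs with one seed produce
byte-identical CSV outputs. Tolerances: share/weight/score conservation
asserted at 1e-9; exact-path local accuracy at 1e-9 and the
per-classifier acceptance bound at 1e-3; Shapley-oracle agreement at
1e-6. HHI input validation requires shares to sum to 1 within 1e-9.
Degenerate inputs (zero-variance features, single-class evaluation sets,
all-zero attributions, empty selections) are handled by the explicit
policies above rather than by numerical accident.

## Benchmark problem sizes

`scripts/acceptance.py` reruns the recovery study (10 replicates at
100/100 × 50 genes), the 200/200 directionality study and the 1000-gene
null calibration, deriving all replicate seeds from one command-line
seed. Attribution settings in the benchmark (background 50 rows, 10
permutation orderings) are the package's chosen accuracy/cost trade-off
for cohorts of this size; local accuracy is exact regardless.

## Known limitations

- Binary diagnosis only; multiclass labels are rejected at validation.
- The Gaussian generator cannot certify performance on raw count data.
- Permutation-sampled attribution splits carry Monte Carlo noise at
  large selected-feature counts; increase `n_permutations` when exact
  enumeration is out of reach and per-feature precision matters.
- The SVM relies on `SVC(probability=True)`, deprecated in scikit-learn
  1.9; a move to `CalibratedClassifierCV` is the obvious forward fix.
- HHI weighting rewards concentration even when it stems from a
  classifier overfitting a single feature; inspecting per-classifier
  shares in the profile CSV is the intended diagnostic.
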