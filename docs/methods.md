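# Methods

## Problem setting

The package frames DILI prediction as four independent binary classification
problems (one per labeling scheme) over a shared set of drugs, each drug
described by (a) perturbation z-scores over a gene universe measured in
several cell lines, with incomplete drug coverage per line, and (b) several
per-drug numeric feature tables. Because the interesting real-world label
sets are imbalanced (roughly 96 positive : 326 negative for a
severity-score label at a 422-drug training scale), every stage is designed
around imbalance: stratified splits and folds, optional minority
resampling, and evaluation by balanced accuracy, MCC and AUC rather than
raw accuracy.

## Signature merging

A ranking is a permutation of the gene universe (rank 1 = most
upregulated); z-score ties are broken by ascending gene identifier so
rankings are reproducible from identical inputs. Cross-cell-line merging is
greedy agglomeration in Kruskal order: compute all pairwise distances among
the current rankings, Borda-merge the closest pair (per-gene mean rank,
re-ranked, mean-ties again by gene identifier), and repeat until one
ranking remains. Merging the closest pair and collapsing the two nodes
reproduces Kruskal's minimum-spanning-tree edge order on the complete
distance graph, which is what "merge each closest neighbor one by one"
describes operationally.

Two rank distances are provided: the Spearman footrule (sum of absolute
rank differences — the default, a true metric on permutations, checked by
property tests) and the squared-deviation alternative. The original
rank-merging software does not document its internal distance, so numerical
equality with it is not claimed; for two inputs any choice reduces to a
plain Borda merge. When several pairs tie at the minimal distance the pair
with the lexicographically smallest (origin-index, origin-index) is merged,
where a merged node carries the smallest origin index among its
constituents; this makes the merge deterministic and, when all pairwise
distances are distinct, invariant to input order. Drugs with no expression
in any cell line are excluded from the expression branch and logged.

## Extreme sets and gene screening

The merged ranking is truncated to extreme sets (top-N and bottom-N; N of
100/250/500/1,000 at full scale, 50/100 at the desk scale) and binarized
into a drugs × genes membership matrix. Each gene is tested against the
binary label with a two-sided Fisher's exact test on the 2×2 table
(member/nonmember × positive/negative); genes with raw p < α (default 0.01)
are retained, sorted by p then identifier.

Choices worth recording:

- **Two-sided test.** Both enrichment and depletion of extreme-set
  membership can mark a DILI-relevant gene, since informative genes are
  planted half up- and half down-regulated and a real signature's direction
  is unknown a priori.
- **No multiple-testing adjustment.** The screen is a predictor filter
  feeding a cross-validated classifier, not an inferential endpoint; the
  raw 0.01 cutoff is the protocol's stated operating point.
- **Constant-membership genes** (all drugs members, or none) carry no
  information and get p = 1 by policy; a zero margin in any 2×2 table also
  yields p = 1.
- The p-value is scipy's hypergeometric two-sided computation, validated
  against exact rational-arithmetic enumeration (`Fraction`-based, no
  floating comparison ambiguity) to 1e-10 on random tables.
- **Calibration note.** Fisher's exact test is conservative on discrete
  data: its attained null selection rate is below α and approaches α only
  as tables grow. Computing the exact attained rate analytically (summing
  the null hypergeometric mass of rejected tables over the membership-count
  distribution) shows ≈0.0075 at 150 drugs but ≈0.0099 at 617 drugs with a
  balanced label and membership probability 1/2. The null-calibration
  checks therefore use that latter design — the full drug count of the
  motivating study with its balanced control class — where the discrete
  test is effectively calibrated.
- Selection uses the **training split only** by default (statistics never
  see test drugs); `whole_data_selection=True` relaxes this for comparison
  with protocols that screen before splitting.

## Tabular preparation and resampling

The prep order is fixed and logged in each FeatureMatrix's provenance:
missing-row removal → zero-variance filter → correlation filter →
derived reporting ratios → (resampling) → standardization. The correlation
filter greedily resolves the worst pair (|Pearson r| > 0.82 by default),
dropping the member with the larger mean absolute correlation to the
remaining columns; ties by column name. The reporting-ratio derivation adds
per-gender DILI-report fractions (DILI events ÷ all events; 0/0 → 0,
logged) under a configurable column mapping, since the exact source-data
formula is underdocumented. Standardization always uses training-set
statistics.

Resamplers:

- **Upsampling** duplicates minority rows with replacement to exact
  balance.
- **SMOTE** interpolates `x_i + u (x_nn − x_i)` with u ~ U(0,1) and x_nn
  among the k = 5 nearest minority neighbors (k reduced with a warning when
  the minority is smaller; a single-row minority is an error). Balance is
  exact; synthetic points provably lie on minority segments.
- **ROSE** is implemented as a smoothed bootstrap: each output row draws a
  class with probability ½, a seed row uniformly within that class, and
  per-feature Gaussian noise with Silverman-style bandwidth
  h_j = (4/((d+2)n_c))^(1/(d+4)) σ_j. This is a documented approximation of
  the cited technique (the reference describes the smoothed bootstrap; the
  bandwidth constant is the standard multivariate-normal rule). The output
  is a fresh sample of the input's size, balanced in expectation; the
  kernel can be shrunk to 0 to recover a plain bootstrap. Synthetic
  per-feature variance equals σ² + h² by convolution, which the tests
  verify at 50,000 draws.

Resampling runs inside training folds by default. `leaky=True` resamples
the full training set before the CV split — the shortcut that lets
duplicated or interpolated copies of validation rows into training. On pure
noise this inflates training CV AUC by ≈0.1 on average (measured by the
acceptance script), which reproduces the overfitting signature reported
when resampled data are validated in-fold.

## Training protocol

Stratified k-fold CV (default 5 folds) repeated R times with a fresh
shuffle per repeat; random search draws hyperparameter configurations
uniformly (log-uniformly for scale parameters) and picks the best mean
validation AUC, ties to the first drawn. AUC, not accuracy, is the
selection criterion throughout, including for ensemble membership. Default
spaces: regularization C log-uniform 1e-3..1e3 (LR, SVMs), polynomial
degree {2,3}, RBF bandwidth log-uniform 1e-4..10, tree depth 1..10, forest
size 100..500, hidden units 1..10 with weight decay log-uniform 1e-5..1.
Degenerate folds (single-class validation or training side) are skipped
with a warning; if every fold degenerates the search errors out.

The full-scale protocol repeats CV 100 times; the desk-scale default is 2–5
repeats and 2–3 candidate draws, and the default algorithm panel is one
representative per family (logistic regression, LDA, decision tree,
Gaussian naive Bayes, RBF SVM) so that a complete pipeline run finishes in
seconds; the registry's heavier members (random forest, the one-hidden-layer
network, the remaining SVM kernels) are enabled by listing them in
`PipelineConfig.algorithms`. Probabilities are whatever the base estimator
emits; no recalibration is applied.

## Evaluation and voting

Sensitivity, specificity, balanced accuracy, MCC and Mann–Whitney AUC
(mid-ranks for ties) are computed from the held-out test split. Undefined
rates (empty class) are reported as 0 with a flag instead of NaN; a zero
factor in the MCC denominator yields 0. Printed tables round to 2 decimals
half-up; the JSON twin is unrounded.

Voting combines the top-k (default 3) models by cross-validated AUC, pooled
across datasets within a DILI class, on the drugs present in every member's
test table. Hard voting resolves exact label ties by falling back to the
soft vote for that drug; score ties resolve to the negative class. The
weighted vote multiplies each member's class probabilities by w/(1 − w)
(its AUC odds) before averaging. The printed form of this rule divides by
(w − 1), which is negative for any AUC < 1 and would systematically invert
the decision; division by (1 − w) is taken as normative because it is the
only reading under which higher-AUC members receive more, not inverted,
influence. The literal form remains available behind
`literal_denominator=True` for comparison. Weights at 1 are clamped to
1 − 1e-6.

## Synthetic study generator

The generator emulates the structural features the pipeline must cope with:

- **Coverage**: a fixed fraction of drugs (default 0.4, matching 247/617)
  is profiled in every cell line; the rest hit each line independently with
  probability 0.7; zero-coverage drugs are allowed and excluded downstream.
- **Labels**: one clinical-like class at the real 96:326 imbalance tied to
  the planted signal; one random control independent of everything; one
  threshold control defined by the median split of a designated
  molecular-weight-like feature (and therefore perfectly predictable from
  it). Class counts are allocated deterministically (⌊fraction·n⌋) and
  shuffled by seed, so counts never vary between runs.
- **Expression**: standard-normal background z-scores; each informative
  gene (default 40 of 800) shifts by ±`gene_effect` in clinical-positive
  drugs, sign fixed per gene with half up and half down so both extreme-set
  tails carry signal.
- **Tabular sets**: three tables mimicking the real predictor families,
  each with planted informative features, one near-duplicate column pair
  (|r| > 0.82) for the correlation filter, gender-stratified event-count
  columns in the adverse-event table, the threshold feature in the
  descriptor table, and missing cells (default rate 0.005, confined to the
  toxicity table, sized so missing-row removal drops a realistic ~15% of
  rows).

All randomness flows from one root seed through named substreams
(coverage / labels / expression / tabular), so components can be
regenerated independently and the whole study is bit-reproducible.

What the generator does **not** emulate: report-count semantics of
adverse-event data (features are generic Gaussians), chemical structure,
dose/time structure (the study collapsed to one dose and time; the
simulator has none), gene–gene correlation, and non-random missingness.
Passing tests therefore demonstrate that the pipeline recovers planted
signal of the assumed form and is calibrated under its null — not that any
particular real dataset is predictable.

## Desk-scale defaults

Default study conditions: 150 drugs, 800 genes, 4 cell lines, signature
sizes N ∈ {50, 100}, 70/30 stratified train/test split per DILI class,
5-fold CV. Null-calibration checks run 200 replicates × 500 genes at the
617-drug balanced design described above; leakage comparisons use 20 seeds
of 120-row, 10-feature noise at 30:90 imbalance. These sizes were chosen so
the complete suite and the acceptance script run in well under a minute
each while keeping every statistical check adequately powered.

## Known limitations

- The Kru-Bor merge recomputes all pairwise distances each round (O(k²·G)
  per drug); fine for single-digit cell-line counts, not tuned for hundreds
  of rankings.
- The correlation filter recomputes the full correlation matrix per
  removal; quadratic in columns, adequate up to a few thousand features.
- SVC probability output relies on internal Platt scaling (soon deprecated
  upstream in favor of explicit calibration wrappers).
- Ensemble members must share test drugs; drugs dropped by one dataset's
  prep (e.g. missing values) are excluded from voting entirely.
- The weighted-vote equation's printed denominator ambiguity cannot be
  resolved from the text; both readings are implemented and the normative
  choice is documented above.
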