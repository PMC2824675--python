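# Methods

## The problem

Gene function prediction is a hierarchical multi-label classification
(HMC) task: a gene may carry many functions at once, and the functions are
organised in a hierarchy — a rooted tree for the MIPS FunCat catalogue
(slash-path names such as `4/3/1`) or a directed acyclic graph for the
Gene Ontology, where a term may have several parents.  Annotations obey
the *hierarchy constraint*: membership in a class implies membership in
every ancestor class.  Sensible predictors must obey it too.

`pcthmc` learns a single decision tree (or a bagged ensemble of trees)
that predicts the entire function vector of a gene at once, and evaluates
predictions with precision/recall analysis suited to the extreme class
imbalance of function catalogues.

## Predictive clustering trees

The label set of example *k* is encoded as a binary vector
v_k ∈ {0,1}^|C| over a fixed class ordering, ancestor-closed by
construction.  A node's heterogeneity is the variance

    Var(S) = (1/|S|) Σ_k d²(v_k, v̄),    d²(a,b) = Σ_i w(c_i) (a_i − b_i)²,

the mean squared *weighted Euclidean distance* to the node's mean vector
v̄.  Class weights decay with depth,

    w(c) = w0 · mean_j w(p_j(c)),        0 < w0 < 1,

where p_j(c) are the parents of c.  The average over the empty parent set
is defined as 1, so top-level classes get weight w0 and, in a rooted tree,
a class at depth d gets exactly w0^(d+1).  The mean over parents makes the
definition well-posed on DAGs.  The decay makes disagreement near the top
of the hierarchy cost more than disagreement at specific leaves.

Induction is standard top-down: at each node every candidate test is
scored by the variance reduction

    ΔVar = Var(S) − (|S_yes|/|S|) Var(S_yes) − (|S_no|/|S|) Var(S_no)

and the best acceptable candidate is installed; otherwise the node becomes
a leaf storing the mean class vector of its examples (the *prototype* —
component i is the fraction of examples annotated with c_i).  Because
training labels are ancestor-closed, prototypes are parent-monotone
(score[parent] ≥ score[child]), so thresholding a prototype with any
threshold map satisfying t_ancestor ≤ t_descendant yields an
ancestor-closed prediction.  Averaging preserves monotonicity, so the same
holds for bagged ensembles.

### Candidate tests

* numeric attribute: `value > t`, with t at the midpoints between
  consecutive distinct observed values;
* binary attribute: `value = 1`;
* nominal attribute: `value ∈ {level}`, one-vs-rest per observed level.

Attributes with fewer than two distinct observed values yield no
candidates.  Candidates are enumerated in a canonical order (attribute
declaration order, then ascending threshold / declared level order).

### Stopping

Two rules stop growth:

* **min_leaf** (default 5): a split is rejected outright if either child
  would hold fewer training examples, enforced during search rather than
  by pruning;
* an **F-test** on the variance reduction.  With weighted sums of squares
  SS = n·Var, the statistic F = (SS_total − SS_within)/(SS_within/(n−2))
  is compared to the upper critical value of F(1, n−2) at the configured
  significance level.  A perfect split (SS_within = 0, SS_total > 0) is
  always accepted; a node with no label variance never splits.  There is
  no post-pruning.

The df(1, n−2) one-way-ANOVA form was chosen because it is exactly
specifiable from the quantities the split criterion already computes; the
significance level is the tunable knob (grid
{0.001, 0.005, 0.01, 0.05, 0.1, 0.125}; see *Tuning* below).

### Numerical choices

* Ties between candidates with equal variance reduction go to the earlier
  candidate in canonical order.  Scores within ~1e−12 relative are treated
  as tied, so mathematically equal candidates computed along different
  arithmetic paths resolve deterministically.
* Missing values follow the branch holding more (non-missing) training
  rows; ties go to the yes-branch.  The winning branch is recorded in the
  node and reused at prediction time, keeping prediction total.
* A score exactly equal to its threshold counts as predicted (≥, not >),
  so a threshold of 1 can still fire on a pure leaf.
* Induction is fully deterministic: identical data and parameters give a
  byte-identical serialized model (canonical JSON, sorted keys).

## Bagging and out-of-bag estimation

`fit_bagging` draws k (default 50) bootstrap replicates (with replacement,
each of the original size n) and trains one tree per replicate; per-tree
RNG streams are spawned by counter from the master seed, so increasing k
extends an ensemble without changing its earlier trees.  Prediction is the
unweighted mean of the k prototype vectors.  Ensembles of this size buy
most of the available benefit; single trees remain available where the
leaf-to-rule readability matters more than accuracy.

Out-of-bag (OOB) estimation scores each training row by averaging only the
trees whose replicate excluded that row (about 36.8% of trees per row in
expectation).  Rows contained in every bag are flagged uncovered and
skipped by evaluation.  OOB scores are computed on raw averaged class
vectors; no thresholding is applied before averaging.

## Evaluation

Function classes are mostly rare, so negatives dominate and ROC analysis
is overly forgiving; PR analysis is primary.  For a class i at threshold
t: TP_i, FP_i, FN_i are counted with "score ≥ t predicts"; correctly
predicted negatives are ignored.  Sweeping t from 1 to 0 over the distinct
scores gives

* the **function-wise PR curve** of class i, and
* the **pooled PR curve** from ΣTP_i, ΣFP_i, ΣFN_i at a common threshold.

Curves are functions of the score multiset only — permuting instances
cannot change them, and a constant-score classifier yields the flat curve
at precision = class frequency.  (A scorer whose output depends on the
order in which genes are processed is defective; this implementation is
the corrected semantics.)

**AUPRC** integrates precision over recall by the trapezoid rule over
achieved points, anchored at recall 0 by carrying the first point's
precision back.  This anchoring makes the constant classifier score
exactly the class frequency and is flag-switchable to hyperbolic
(Davis–Goadrich) interpolation in TP/FP space for users who prefer it;
the two differ visibly only on very sparse curves.

Three scalar summaries: AU(pooled-PR) (frequency-weighted: frequent,
shallow classes dominate), the unweighted mean per-class AUPRC, and the
mean per-class AUROC (plain Mann–Whitney; classes with no negative test
instance are excluded from the ROC mean).  Classes with zero positive test
instances admit no recall and are excluded from per-class means; their
count is reported.  An optional stratification groups the per-class table
by training-set specificity (3–10, 11–30, 31–100, 101–300 training
positives).

## Tuning the significance level

`tune_significance` holds out 1/3 of the training data (stratified by
whether an instance carries any annotation — the paperwork of stratifying
by full label sets is not meaningful when most label sets are unique),
trains one model per candidate level, picks the one maximising validation
AU(pooled-PR) (ties to the smaller, more stringent level), and retrains on
the full training set with the winner.

## The synthetic benchmark generator

`synthetic` grows a random rooted forest (each new class attaches to a
random earlier class below the depth cap; with configurable probability it
gains a second parent, giving a DAG) and plants one-condition rules
`x_a > θ → class c` on childless classes.  Thresholds rise with depth
(θ ≈ 1 − 0.5·0.65^depth ± 0.05), so deeper classes are rarer, as in real
catalogues.  Labels are ancestor-closed after rule application.  Label
noise flips each positive bit off with the configured rate, compensates
with a random bit flipped on, and re-closes ancestors — inputs therefore
always satisfy the hierarchy constraint and the configured rate is an
effective pre-closure rate.

Two options exist specifically for parameter-recovery experiments:

* `distinct_rule_attributes` samples rule attributes without replacement.
  Two rules on one attribute with near-identical thresholds are not
  identifiable from data, which would make "recovery" ill-posed.
* `attr_step` quantises numeric attributes to a grid (features recorded at
  finite measurement resolution).  With continuous attributes the learned
  midpoint threshold and the generating threshold always bracket an
  interval that unseen data can fall into, so held-out performance cannot
  be exactly perfect even when every rule is found; with a sufficiently
  coarse grid every node observes both gap neighbours and recovery is
  exact.  Recovery checks ask that a learned threshold partitions its
  node's rows exactly as the generating threshold does.

The generator does **not** emulate correlated genomic features (homology
e-values, expression profiles), realistic missingness, or dependence
between classes beyond the hierarchy itself.  Green tests on this data
demonstrate algorithmic correctness and the qualitative ensemble/noise
behaviour, not expected accuracy on any real organism.

## Experiment sizes used by the test suite and acceptance script

Chosen to exercise every claim at desk scale: oracle-equivalence over 200
random datasets of ≤50 rows; hierarchy-consistency over 100 models × 1,000
instances; ensemble-benefit over 20 replicates of 600 train / 300 test
rows with 20% label noise and k = 50; OOB vs holdout at n = 1,000 and
k = 10 (the setting used when comparing against out-of-bag protocols in
the literature); recovery at n = 2,000 with 5 planted rules.

## Known limitations

* Binary splits only; no multi-way or oblique tests, no cost-complexity
  pruning, no random-forest-style feature subsampling.
* The ARFF reader supports a plain subset (numeric / nominal / binary
  attributes plus a string label column), not any richer dialect.
* The hierarchy edge-list reader treats all edge types identically; OBO
  niceties (relationship filtering, obsolete terms) are out of scope.
* The exact F-test convention of other HMC tree implementations may
  differ; numeric agreement with them is not claimed.
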