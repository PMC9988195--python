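# Methods

## Scope and data model

`dtgraph` implements binary decision-tree classification on typed tabular
data with a single categorical class-label column, plus the machinery
around it: typed ingestion (CSV and property-graph node buckets),
evaluation (k-fold cross-validation, confusion-matrix metrics), per-level
feature analysis, property-graph persistence, and seeded synthetic
fixtures. The in-memory container is a pandas DataFrame wrapped by
`Dataset`, which fixes the conventions the algorithms rely on: numerical
columns are float64 with NaN as the missing marker, categorical columns
are strings with None as the missing marker, the class column is always
categorical and never missing, and column order is the header order —
which is also the deterministic tie-breaking order downstream.

Column types are inferred, not declared: a column is numerical iff every
non-missing cell parses as a finite real under a fixed locale-independent
dialect (optional sign, decimal or integer notation, optional scientific
exponent; `inf`/`nan` and underscore separators are rejected). The empty
string and the literal `NA` both mean missing. The class column is forced
categorical even when its values parse numerically, because outcome codes
such as `0`/`1` are labels, not quantities.

## Splitting criteria

All splits are binary. For a node with class proportions `p_i`:

* Gini impurity `G = 1 − Σ p_i²`, bounded by `[0, 1 − 1/k]`;
* Shannon entropy `H = −Σ p_i log₂ p_i` in bits, bounded by `[0, log₂ k]`,
  with `0·log 0 ≡ 0`.

A candidate partition of a parent into branches `b` with weights
`w_b = n_b/n` is scored as

* `gini`: `G(parent) − Σ w_b G(b)` (impurity decrease),
* `information_gain`: `H(parent) − Σ w_b H(b)`,
* `gain_ratio`: information gain divided by the split information
  `−Σ w_b log₂ w_b`, defined as 0 when the split information is 0 (one
  branch empty). Degenerate partitions score 0 under all three criteria.

Logarithms are base 2 throughout (scores in bits). Numeric candidate
thresholds sit at midpoints between consecutive distinct sorted values,
with the agreeing branch `value ≤ threshold`; a guard reassigns the
threshold to the lower value in the (float-adjacent) case where the
midpoint rounds up to the upper value, so both branches stay non-empty.
Categorical candidates are one-vs-rest equality tests on each observed
category; subset splits are deliberately out of scope (exponential, and a
single agree/disagree test matches the binary-split model).

The search is exhaustive over all features and candidates. Comparisons use
exact floating `>` with a fixed enumeration order, so ties resolve
deterministically: earlier schema column first, then lower threshold, then
lexicographically smaller category. A node whose best score is ≤ 0 becomes
a leaf — this zero-gain stop is a design choice (the alternative, stopping
only on purity/depth, can recurse without progress).

### Missing values

Gini and gain ratio tolerate missing feature values: rows missing the
split feature are excluded from that feature's score, and at partition
time are routed to the branch holding the majority of the non-missing rows
(ties route to the agreeing branch). The routing is recorded on the node,
so prediction treats a missing value exactly as training did. Information
gain does not handle missing values and raises `MissingValueError` when
any feature cell is missing. This asymmetric capability is a modelling
commitment of the three-criteria family implemented here; the routing
mechanism itself (majority routing rather than surrogate splits or
fractional instances) was chosen for determinism and simplicity.

## Tree induction, pruning, prediction

Induction is greedy recursion: emit a leaf (majority label, ties to the
lexicographically smallest) when the node is pure, when no positive-score
split exists, or — with pre-pruning enabled — when the node sits at
`max_depth` decision levels. `max_depth` counts decision levels, so
`max_depth = 0` yields a single leaf. Node ids are assigned in pre-order
(`n0`, `n1`, …), which makes the exported graph stable across runs.
Training touches each row once per level, giving the usual
`O(dim · n log n)`-flavoured cost on balanced data; a smoke test asserts
logarithmic realized depth on segment-labelled data, not a wall-clock
benchmark.

Prediction is deterministic traversal; text inputs (e.g. CSV rows from the
CLI `predict` command) are coerced with the same numeric dialect as
ingestion. Feature analysis re-runs induction with a recorder, emitting
one record per candidate feature per decision node (the feature's best
score at that node, with the chosen feature flagged), ordered by level,
node creation order, then schema order.

## Evaluation

The confusion matrix is actual-by-predicted over a sorted label set.
Accuracy is trace over total. MCC uses the multiclass R_k form
`(c·s − Σ p_k t_k) / √((s² − Σ p_k²)(s² − Σ t_k²))` with `c` the trace,
`s` the total, `t`/`p` the row/column sums; at two classes this reduces
algebraically to the familiar `(TP·TN − FP·FN)/√(…)` (property-tested, and
cross-checked against scikit-learn). Zero denominators yield 0 by
convention, as does collapsed precision when nothing is predicted
positive. Collapsed precision merges a k×k matrix to 2×2 over a proper
non-empty positive label subset and reports `TP/(TP+FP)` — the view used
for three-class outcomes read as *positive condition vs rest*.

k-fold CV shuffles row indices with a seeded generator and cuts contiguous
blocks of size `⌈n/k⌉`/`⌊n/k⌋`; each fold is predicted by a tree trained
on the complement, and per-fold predictions are pooled into a single
matrix before computing metrics (micro aggregation). Folds are not
stratified by default; a stratified option deals per-class shuffled rows
cyclically across folds for heavily imbalanced data. Reported generation
times are informational and never asserted.

## Property-graph persistence

A tree maps to a bucket of node records (`DTDecision` with feature,
condition kind, threshold/category, level, missing-routing;
`DTLeaf` with label, level, and the training class distribution as
parallel `class_labels`/`class_counts` arrays — JSON-portable scalars and
arrays only) and relationship records (`TRUE_BRANCH`/`FALSE_BRANCH`, each
carrying a `missing_routed` flag). Validation enforces the rooted-binary-
tree invariants: unique ids, no dangling endpoints,
`|relationships| = |nodes| − 1`, unique parents, a single root, exactly
one TRUE and one FALSE branch per decision node, and arborescence
(networkx). Reloading reconstructs a tree whose predictions equal the
original's on every row; training metadata (criterion, max_depth) is not
part of the bucket schema, so reloaded trees carry `None` there.

The Cypher emission is a deterministic script — one `CREATE` per node,
then one `MATCH`-by-id plus `CREATE` per relationship, nodes ordered by
id and relationships by source then branch type — so identical buckets
emit byte-identical text loadable in a stock graph-database shell. String
values are single-quoted with backslash escaping; keys are backtick-
quoted. GraphML export flattens list-valued properties to JSON strings
(GraphML attributes are scalar).

## Synthetic fixtures

The generator emulates the *shapes* of clinical classification datasets —
instance counts, feature counts and type mixes, exact class counts (or
proportions resolved by deterministic largest-remainder rounding),
missingness rates — from simple parametric families (uniform, normal,
lognormal, multinomial). Four presets mirror published dataset shapes:
a 299×13 binary heart-failure cohort (96/203), a 48×51 three-class
metaproteome panel (20/13/15), a 1,485×12 binary respiratory-infection
table (1,072/413, 5% missing cells), and a 253,680×22 three-class survey
(213,703/4,631/35,346). Numeric features optionally receive a small
per-class mean shift so trees have signal to find; otherwise features are
independent of the label. What the fixtures deliberately do **not**
emulate: real covariance structure, nonlinear risk interactions beyond the
planted rule, informative missingness, or the biology behind the
variables. Passing tests on these fixtures therefore demonstrates
correctness of the algorithms and contracts, not clinical performance on
the real datasets.

Planted-rule datasets label rows by a deterministic predicate over at most
two features, optionally flipping labels at a noise rate. The default
conjunction fixture — class 1 iff BMI > 30 and high blood pressure — draws
BMI from the midpoints of four clinical bands (22/27/32/37) with
hypertension prevalence 0.7 and three label-independent noise features.
The coarse bands are essential to the recovery guarantee: each band is
well-populated at the default n = 200, so the learned threshold between 27
and 32 cannot drift past a neighbouring band, and no chance-pure block
above the boundary can lure the greedy root to a spurious threshold (with
a continuous BMI either failure occurs in a substantial fraction of
seeds). Recovery — the depth-2 pruned tree using exactly the planted pair
and cross-validating at accuracy 1.0 — then holds by construction, which
the acceptance suite verifies over 20 seeds.

`balanced_subsample` downsamples every class without replacement to the
minority count with a seeded generator and shuffles the result; on the
survey preset this yields 3 × 4,631 = 13,893 rows. The sampling method is
a design choice (only the resulting counts are externally fixed).

## Numerical and interface choices

* Train/test splitting rounds the train size half-up; extreme fractions
  may leave one side empty (the partition contract still holds).
* Random sources are numpy `default_rng` seeded explicitly everywhere;
  identical inputs and seeds give byte-identical outputs (CSV fixtures,
  Cypher scripts, reports minus the timing field).
* The CLI mirrors the five procedure families (cross-validation, training
  from CSV, training from nodes, confusion-matrix-only, feature analysis)
  plus simulate/predict/export; flags override a YAML config file, which
  overrides defaults. Cross-validation writes a report only — trees are
  persisted by the training commands.
* Problem sizes in the test and acceptance runs (n ≤ 30 oracle datasets,
  200-row planted fixtures, the full 253,680-row survey preset) were
  chosen as the smallest sizes at which each property is meaningful and
  stable.

## Known limitations

No post-pruning, ensembles, probability outputs, surrogate splits, or
multiway/subset categorical splits. One-vs-rest categorical splits can
need several levels where a subset split would need one. The zero-gain
stop means XOR-style joint effects with zero marginal gain are not split
on. Collapsed precision is the only collapsed metric (no recall/F1/AUC).
The optional live graph-database adapter surface (push/pull of buckets) is
not implemented; buckets are exchanged as files.
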