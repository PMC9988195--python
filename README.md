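# dtgraph

Binary decision-tree induction for clinical-style tabular data, with the
trained classifier persisted as a **property graph** — the node/relationship
form a graph database stores, queries and visualizes.

Clinical datasets (patient demographics, lab values, survey indicators) are
increasingly kept in graph databases as *homogeneous, unconnected nodes*:
one node per patient, one property per variable, no relationships.
`dtgraph` trains decision trees on exactly that kind of data — read either
from CSV files or from JSON buckets of such nodes — evaluates them with
k-fold cross-validation, and writes the fitted tree back out as a graph
(JSON bucket, Cypher `CREATE` script, or GraphML) so it can be stored next
to the data, inspected visually, and reused for inference.

## The model

Trees are binary: each decision node tests one feature, one branch agreeing
with the condition (numeric `value ≤ threshold`, categorical
`value = category`) and the other disagreeing. Growth recursively takes the
best-scoring admissible split under one of three criteria:

- **Gini index** (CART): impurity `G = 1 − Σᵢ pᵢ²`, split scored by the
  weighted impurity decrease `G(parent) − Σ_b (n_b/n) G(b)`;
- **Information gain** (ID3): entropy `H = −Σᵢ pᵢ log₂ pᵢ` in bits, scored
  by `H(parent) − Σ_b (n_b/n) H(b)`;
- **Gain ratio** (C4.5): information gain normalised by the split
  information `−Σ_b (n_b/n) log₂(n_b/n)`.

Numeric candidate thresholds sit at midpoints between consecutive distinct
values; categorical splits are one-vs-rest. Growth stops at pure nodes, at
zero-gain nodes, or — with pre-pruning — at `max_depth` decision levels,
where the impure leaf takes the majority class. Rows missing the split
feature are excluded from scoring and routed with the majority of the
non-missing rows (information gain instead rejects missing values, which it
cannot handle).

Evaluation reports the confusion matrix, accuracy, the Matthews correlation
coefficient (multiclass R_k generalisation), and — for multi-class problems
collapsed onto a clinically meaningful positive set, e.g. *any diabetes vs
none* — a collapsed 2×2 precision. Cross-validation pools per-fold
predictions into one matrix.

A seeded synthetic-data module generates clinical-shape fixtures (instance
counts, feature mixes, class imbalance, missingness), planted-rule datasets
with a known ground-truth pair of risk factors, and minority-class balanced
subsamples for imbalance handling.

## Worked example

Simulate a 200-patient cohort whose outcome follows a planted rule —
class 1 iff BMI > 30 **and** high blood pressure — cross-validate, train,
and persist the tree:

```console
$ dtgraph simulate --planted --n 200 --seed 11 --out cohort.csv
simulate: planted bmi/highBP rule, n=200 -> cohort.csv
$ dtgraph cv --input cohort.csv --label outcome --criterion gini \
    --folds 5 --seed 11 --prune --max-depth 2 --out cv.json
cv: n=200 folds=5 accuracy=1.0000 mcc=1.0000 -> cv.json
$ dtgraph simulate --planted --n 80 --seed 12 --out newpatients.csv
$ dtgraph train --train cohort.csv --test newpatients.csv --label outcome \
    --criterion gain_ratio --prune --max-depth 2 --out model
train: n_train=200 n_test=80 depth=2 accuracy=1.0000 mcc=1.0000 -> model.json, model.cypher, model.report.json
```

Pooled CV accuracy and MCC of 1.0 say the depth-2 tree classifies every
held-out patient correctly — expected here, because the rule is noiseless
and depth-2 learnable. The persisted Cypher script starts:

```cypher
CREATE (:`DTDecision` {`id`: 'n0', `feature`: 'bmi', `kind`: 'numeric_threshold', `level`: 0, `missing_branch`: 'true', `threshold`: 29.5});
CREATE (:`DTLeaf` {`id`: 'n1', `label`: '0', `level`: 1, `class_labels`: ['0'], `class_counts`: [112]});
CREATE (:`DTDecision` {`id`: 'n2', `feature`: 'highBP', `kind`: 'categorical_equality', `level`: 1, `missing_branch`: 'false', `category`: 'no'});
```

— the root splits on BMI, the second level on blood pressure: exactly the
planted risk factors. Feature analysis makes that quantitative, listing
every candidate feature's criterion value at each decision node:

```console
$ dtgraph feature-analysis --input cohort.csv --label outcome \
    --prune --max-depth 2 --out fa.csv
$ head -4 fa.csv
level,node_id,feature,criterion_value,chosen
0,n0,bmi,0.2771999999999999,true
0,n0,highBP,0.10249411764705862,false
0,n0,age,0.004511557788944742,false
```

At the root, BMI's impurity decrease (0.277) dwarfs every other feature;
at the next level high blood pressure dominates (0.375). `dtgraph predict
--bucket model.json --input newpatients.csv --out preds.csv` classifies new
rows from the stored graph alone.

The same operations are available as a library (`dtgraph.build_tree`,
`cross_validate`, `tree_to_graph`, …) and accept node-bucket JSON input via
`dtgraph train-nodes`.

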