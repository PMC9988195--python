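"""Recursive binary decision-tree induction, prediction and feature analysis.

Induction recursively takes the best-scoring admissible binary split
(see :mod:`dtgraph.splitting`) and stops at pure nodes, at nodes without a
positive-score split, or -- with pre-pruning enabled -- at ``max_depth``
decision levels, emitting a leaf labelled with the majority class.

Rows missing the split feature are routed to the branch that received the
majority of the non-missing rows; that routing is recorded on the node so
prediction treats missing values identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .splitting import (
    CATEGORICAL_EQUALITY,
    NUMERIC_THRESHOLD,
    ClassDistribution,
    CriterionKind,
    MissingValueError,
    SplitCandidate,
    feature_best_splits,
)
from .tabular_io import NUMERICAL, Dataset, is_missing_cell, parse_numeric

TRUE_BRANCH = "true"
FALSE_BRANCH = "false"


@dataclass
class LeafNode:
    """A terminal node carrying the majority label of its training rows."""

    node_id: str
    label: str
    distribution: ClassDistribution
    level: int


@dataclass
class DecisionNode:
    """An internal node testing one feature against a threshold or category.

    ``missing_branch`` records where rows without a value for ``feature``
    were routed during training ("true" or "false").
    """

    node_id: str
    feature: str
    kind: str
    level: int
    true_child: "TreeNode"
    false_child: "TreeNode"
    threshold: float | None = None
    category: str | None = None
    missing_branch: str = TRUE_BRANCH


TreeNode = Union[DecisionNode, LeafNode]


@dataclass
class DecisionTree:
    """A trained binary classifier.

    ``criterion`` and ``max_depth`` are training metadata; trees reloaded
    from a persisted property graph carry None there (the structure alone
    determines predictions).
    """

    root: TreeNode
    criterion: CriterionKind | None
    class_labels: tuple[str, ...]
    max_depth: int | None
    depth: int


@dataclass
class FeatureLevelRecord:
    """Best criterion value of one feature at one decision node."""

    level: int
    node_id: str
    feature: str
    criterion_value: float
    chosen: bool


def majority_label(dist: ClassDistribution) -> str:
    """The label with the maximal count; ties go to the lexicographically
    smallest label."""
    if dist.total == 0:
        raise ValueError("majority label of an empty distribution is undefined")
    top = max(dist.counts.values())
    return min(label for label, count in dist.counts.items() if count == top)


def node_depth(node: TreeNode) -> int:
    if isinstance(node, LeafNode):
        return 0
    return 1 + max(node_depth(node.true_child), node_depth(node.false_child))


def _induce(
    train: Dataset,
    criterion: CriterionKind,
    prune: bool,
    max_depth: int | None,
    recorder: list[FeatureLevelRecord] | None,
) -> DecisionTree:
    criterion = CriterionKind(criterion)
    if train.n == 0:
        raise ValueError("cannot build a tree from an empty training set")
    if prune:
        if max_depth is None or max_depth < 0:
            raise ValueError("pruning requires max_depth >= 0")
    if criterion is CriterionKind.INFORMATION_GAIN and train.has_missing_features():
        raise MissingValueError(
            "information gain cannot handle missing feature values"
        )
    ids = itertools.count()
    schema_rank = {name: i for i, name in enumerate(train.feature_names)}

    def grow(data: Dataset, level: int) -> TreeNode:
        node_id = f"n{next(ids)}"
        dist = ClassDistribution.from_labels(data.class_values)
        if dist.is_pure() or (prune and level == max_depth):
            return LeafNode(node_id, majority_label(dist), dist, level)
        per_feature = feature_best_splits(data, criterion)
        best: SplitCandidate | None = None
        for cand in per_feature:
            if best is None or cand.score > best.score:
                best = cand
        if best is None or best.score <= 0.0:
            return LeafNode(node_id, majority_label(dist), dist, level)
        if recorder is not None:
            for cand in sorted(per_feature, key=lambda c: schema_rank[c.feature]):
                recorder.append(
                    FeatureLevelRecord(
                        level=level,
                        node_id=node_id,
                        feature=cand.feature,
                        criterion_value=cand.score,
                        chosen=cand.feature == best.feature,
                    )
                )
        column = data.column(best.feature)
        missing = column.isna().to_numpy()
        if best.kind == NUMERIC_THRESHOLD:
            agree = (column.to_numpy(dtype=np.float64) <= best.threshold) & ~missing
        else:
            agree = (column.to_numpy(dtype=object) == best.category) & ~missing
        disagree = ~agree & ~missing
        n_true = int(agree.sum())
        n_false = int(disagree.sum())
        missing_branch = TRUE_BRANCH if n_true >= n_false else FALSE_BRANCH
        if missing_branch == TRUE_BRANCH:
            agree = agree | missing
        else:
            disagree = disagree | missing
        true_rows = np.nonzero(agree)[0].tolist()
        false_rows = np.nonzero(disagree)[0].tolist()
        node = DecisionNode(
            node_id=node_id,
            feature=best.feature,
            kind=best.kind,
            level=level,
            true_child=None,  # type: ignore[arg-type]  -- filled below
            false_child=None,  # type: ignore[arg-type]
            threshold=best.threshold,
            category=best.category,
            missing_branch=missing_branch,
        )
        node.true_child = grow(data.subset(true_rows), level + 1)
        node.false_child = grow(data.subset(false_rows), level + 1)
        return node

    root = grow(train, 0)
    return DecisionTree(
        root=root,
        criterion=criterion,
        class_labels=tuple(sorted(train.class_counts())),
        max_depth=max_depth if prune else None,
        depth=node_depth(root),
    )


def build_tree(
    train: Dataset,
    criterion: CriterionKind,
    prune: bool = False,
    max_depth: int | None = None,
) -> DecisionTree:
    """Induce a binary decision tree on *train*.

    With ``prune=True`` growth stops at ``max_depth`` decision levels
    (``max_depth=0`` yields a single leaf) and impure nodes at the cap
    take the majority class label.
    """
    return _induce(train, criterion, prune, max_depth, recorder=None)


def feature_analysis(
    train: Dataset,
    criterion: CriterionKind,
    prune: bool = False,
    max_depth: int | None = None,
) -> list[FeatureLevelRecord]:
    """Per-level feature scores collected while the tree is generated.

    For every decision node the tree creates, one record per candidate
    feature holds that feature's best split score at the node; the
    selected feature is flagged ``chosen``.  Records are ordered by level,
    then node creation order, then schema column order.
    """
    records: list[FeatureLevelRecord] = []
    _induce(train, criterion, prune, max_depth, recorder=records)
    creation = {}
    for rec in records:
        creation.setdefault(rec.node_id, len(creation))
    records.sort(key=lambda r: (r.level, creation[r.node_id]))
    return records


def _row_value(row: Mapping[str, object], feature: str) -> object:
    value = row.get(feature)
    return None if is_missing_cell(value) else value


def predict(tree: DecisionTree, row: Mapping[str, object]) -> str:
    """Classify one row by deterministic traversal to a leaf.

    Numeric conditions take the true branch iff ``value <= threshold``;
    categorical iff ``value == category`` (string comparison).  A missing
    value follows the branch recorded at training time.
    """
    node = tree.root
    while isinstance(node, DecisionNode):
        value = _row_value(row, node.feature)
        if value is None:
            branch = node.missing_branch == TRUE_BRANCH
        elif node.kind == NUMERIC_THRESHOLD:
            if isinstance(value, str):
                parsed = parse_numeric(value)
                if parsed is None:
                    raise ValueError(
                        f"non-numeric value {value!r} for feature "
                        f"{node.feature!r}"
                    )
                value = parsed
            branch = float(value) <= node.threshold
        else:
            branch = str(value) == node.category
        node = node.true_child if branch else node.false_child
    return node.label


def predict_dataset(tree: DecisionTree, data: Dataset) -> list[str]:
    """Predicted label per row of *data*, in row order."""
    return [predict(tree, row) for row in data.rows()]
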