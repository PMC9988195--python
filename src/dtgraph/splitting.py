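"""Impurity mathematics and exhaustive binary-split search.

Three splitting criteria are supported, matching the classic CART / ID3 /
C4.5 families:

* ``gini`` -- weighted decrease of the Gini impurity ``1 - sum p_i^2``;
* ``information_gain`` -- decrease of Shannon entropy ``-sum p_i log2 p_i``
  (bits);
* ``gain_ratio`` -- information gain normalised by the split information,
  the entropy of the branch-size distribution.

All trees are binary.  Numeric features split at midpoints between
consecutive distinct values ("agree" branch: value <= threshold);
categorical features split one-vs-rest on a single category ("agree"
branch: value == category).

Missing values: for gini and gain ratio, rows missing the split feature
are excluded from scoring (tree induction later routes them to the branch
holding the majority of non-missing rows).  Information gain cannot handle
missing values and rejects them outright with :class:`MissingValueError`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

from .tabular_io import NUMERICAL, Dataset

NUMERIC_THRESHOLD = "numeric_threshold"
CATEGORICAL_EQUALITY = "categorical_equality"


class CriterionKind(str, Enum):
    """Splitting criterion selector."""

    GINI = "gini"
    INFORMATION_GAIN = "information_gain"
    GAIN_RATIO = "gain_ratio"


class MissingValueError(ValueError):
    """Raised when a criterion cannot handle missing feature values."""


@dataclass
class ClassDistribution:
    """Non-negative class-label counts at a node."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, count in self.counts.items():
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ValueError(f"invalid count for {label!r}: {count!r}")
        self.counts = {k: int(v) for k, v in self.counts.items()}

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "ClassDistribution":
        return cls(dict(Counter(labels)))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def is_pure(self) -> bool:
        return sum(1 for c in self.counts.values() if c > 0) <= 1

    def nonzero(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if v > 0}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassDistribution):
            return NotImplemented
        return self.nonzero() == other.nonzero()


@dataclass
class SplitCandidate:
    """A proposed binary partition of a node with its criterion score.

    Exactly one of ``threshold`` (numeric kind) or ``category``
    (categorical kind) is set.  ``left`` collects the rows agreeing with
    the condition (value <= threshold, or value == category); ``right``
    the rows disagreeing.  Rows missing the feature appear in neither.
    """

    feature: str
    kind: str
    score: float
    left: ClassDistribution
    right: ClassDistribution
    threshold: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.kind == NUMERIC_THRESHOLD:
            if self.threshold is None or self.category is not None:
                raise ValueError("numeric candidate needs a threshold only")
        elif self.kind == CATEGORICAL_EQUALITY:
            if self.category is None or self.threshold is not None:
                raise ValueError("categorical candidate needs a category only")
        else:
            raise ValueError(f"unknown split kind: {self.kind!r}")


def gini_impurity(dist: ClassDistribution) -> float:
    """Gini impurity ``1 - sum p_i^2``; 0 iff pure, at most ``1 - 1/k``."""
    total = dist.total
    if total == 0:
        raise ValueError("Gini impurity of an empty distribution is undefined")
    return 1.0 - sum((c / total) ** 2 for c in dist.counts.values())


def entropy(dist: ClassDistribution) -> float:
    """Shannon entropy ``-sum p_i log2 p_i`` in bits; ``0 log 0 == 0``."""
    total = dist.total
    if total == 0:
        raise ValueError("entropy of an empty distribution is undefined")
    acc = 0.0
    for count in dist.counts.values():
        if count > 0:
            p = count / total
            acc -= p * math.log2(p)
    return acc


def _check_partition(
    parent: ClassDistribution, left: ClassDistribution, right: ClassDistribution
) -> None:
    labels = set(parent.counts) | set(left.counts) | set(right.counts)
    for label in labels:
        if left.counts.get(label, 0) + right.counts.get(label, 0) != parent.counts.get(
            label, 0
        ):
            raise ValueError("child distributions inconsistent with parent")


def partition_score(
    parent: ClassDistribution,
    left: ClassDistribution,
    right: ClassDistribution,
    criterion: CriterionKind,
) -> float:
    """Score a binary partition of *parent* under the given criterion.

    gini: impurity decrease; information_gain: entropy decrease (bits);
    gain_ratio: information gain over split information, defined as 0 when
    the split information is 0 (one branch empty).
    """
    if parent.total == 0:
        raise ValueError("cannot score a partition of an empty parent")
    _check_partition(parent, left, right)
    criterion = CriterionKind(criterion)
    n = parent.total
    branches = [b for b in (left, right) if b.total > 0]
    if criterion is CriterionKind.GINI:
        children = sum(b.total / n * gini_impurity(b) for b in branches)
        return gini_impurity(parent) - children
    gain = entropy(parent) - sum(b.total / n * entropy(b) for b in branches)
    if criterion is CriterionKind.INFORMATION_GAIN:
        return gain
    split_info = -sum(
        (b.total / n) * math.log2(b.total / n) for b in branches
    )
    if split_info == 0.0:
        return 0.0
    return gain / split_info


def enumerate_candidate_splits(
    data: Dataset, feature: str, criterion: CriterionKind = CriterionKind.GINI
) -> list[SplitCandidate]:
    """All admissible binary splits of *data* on one feature, scored.

    Numeric features yield one candidate per midpoint between consecutive
    distinct sorted non-missing values (ascending threshold order);
    categorical features one candidate per distinct non-missing category
    (lexicographic order).  Candidates with an empty branch are excluded,
    as are rows missing the feature value.
    """
    col_schema = data.schema_for(feature)
    if col_schema.is_class_label:
        raise ValueError("cannot split on the class-label column")
    criterion = CriterionKind(criterion)
    column = data.column(feature)
    labels = data.class_values
    mask = column.notna().to_numpy()
    y = labels.to_numpy(dtype=object)[mask]
    if y.size < 2:
        return []
    parent = ClassDistribution.from_labels(y)
    class_order = sorted(parent.counts)
    class_index = {label: i for i, label in enumerate(class_order)}
    y_idx = np.array([class_index[label] for label in y])

    candidates: list[SplitCandidate] = []
    if col_schema.kind == NUMERICAL:
        values = column.to_numpy(dtype=np.float64)[mask]
        order = np.argsort(values, kind="stable")
        vs = values[order]
        ys = y_idx[order]
        # cumulative per-class counts over the sorted rows
        onehot = np.zeros((vs.size, len(class_order)), dtype=np.int64)
        onehot[np.arange(vs.size), ys] = 1
        cum = np.cumsum(onehot, axis=0)
        parent_counts = cum[-1]
        boundaries = np.nonzero(vs[:-1] < vs[1:])[0]
        for i in boundaries:
            threshold = (vs[i] + vs[i + 1]) / 2.0
            if threshold >= vs[i + 1]:  # guard midpoint rounding up
                threshold = vs[i]
            left_counts = cum[i]
            right_counts = parent_counts - left_counts
            left = ClassDistribution(
                {c: int(left_counts[j]) for j, c in enumerate(class_order)}
            )
            right = ClassDistribution(
                {c: int(right_counts[j]) for j, c in enumerate(class_order)}
            )
            score = partition_score(parent, left, right, criterion)
            candidates.append(
                SplitCandidate(
                    feature=feature,
                    kind=NUMERIC_THRESHOLD,
                    score=score,
                    left=left,
                    right=right,
                    threshold=float(threshold),
                )
            )
    else:
        values = column.to_numpy(dtype=object)[mask]
        for category in sorted(set(values)):
            agree = values == category
            if agree.all() or not agree.any():
                continue
            left = ClassDistribution.from_labels(y[agree])
            right = ClassDistribution.from_labels(y[~agree])
            score = partition_score(parent, left, right, criterion)
            candidates.append(
                SplitCandidate(
                    feature=feature,
                    kind=CATEGORICAL_EQUALITY,
                    score=score,
                    left=left,
                    right=right,
                    category=str(category),
                )
            )
    return candidates


def feature_best_splits(
    data: Dataset, criterion: CriterionKind
) -> list[SplitCandidate]:
    """Best candidate per feature (schema order); features lacking any
    admissible candidate are omitted.  Within a feature, ties keep the
    lower threshold / lexicographically smaller category."""
    criterion = CriterionKind(criterion)
    if criterion is CriterionKind.INFORMATION_GAIN and data.has_missing_features():
        raise MissingValueError(
            "information gain cannot handle missing feature values"
        )
    bests: list[SplitCandidate] = []
    for feature in data.feature_names:
        best: SplitCandidate | None = None
        for cand in enumerate_candidate_splits(data, feature, criterion):
            if best is None or cand.score > best.score:
                best = cand
        if best is not None:
            bests.append(best)
    return bests


def best_split(data: Dataset, criterion: CriterionKind) -> SplitCandidate | None:
    """The highest-scoring admissible split over all features, or None.

    Returns None when no admissible candidate exists or the best score is
    <= 0.  Ties break deterministically: earlier schema column first, then
    lower threshold, then lexicographically smaller category.
    """
    if not data.feature_names:
        raise ValueError("dataset has no non-class feature")
    best: SplitCandidate | None = None
    for cand in feature_best_splits(data, criterion):
        if best is None or cand.score > best.score:
            best = cand
    if best is None or best.score <= 0.0:
        return None
    return best
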