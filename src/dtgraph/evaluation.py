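"""Classifier evaluation: k-fold cross-validation and quality metrics.

The confusion matrix is the central object (rows = actual labels,
columns = predicted).  Accuracy is its trace over its total; the Matthews
correlation coefficient uses the multiclass R_k generalisation, which
reduces to the familiar binary formula at two classes.  For three-class
problems collapsed onto a clinically meaningful positive set (e.g. any
diabetes vs none), :func:`collapsed_precision` merges the matrix to 2x2
and reports TP / (TP + FP).

Cross-validation pools the per-fold predictions into a single confusion
matrix (micro aggregation) before computing metrics.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .splitting import CriterionKind
from .tabular_io import Dataset
from .tree import DecisionTree, build_tree, predict_dataset


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted label counts over an ordered label set."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a labels x labels square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_lists(self) -> list[list[int]]:
        return self.counts.tolist()


@dataclass
class EvaluationReport:
    """Confusion matrix plus summary metrics for one evaluation run."""

    matrix: ConfusionMatrix
    accuracy: float
    mcc: float
    precision_collapsed: float | None = None
    generation_time: float = 0.0  # seconds; informational only

    def to_dict(self) -> dict:
        payload = {
            "labels": list(self.matrix.labels),
            "matrix": self.matrix.to_lists(),
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "generation_time_s": self.generation_time,
        }
        if self.precision_collapsed is not None:
            payload["precision_collapsed"] = self.precision_collapsed
        return payload

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass
class FoldAssignment:
    """A seeded partition of row indices into k near-equal folds."""

    fold_of_row: np.ndarray
    k: int
    seed: int

    def rows_in_fold(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold_of_row == fold)[0]


def k_fold_indices(n: int, k: int, seed: int) -> FoldAssignment:
    """Assign n rows to k folds: seeded shuffle, then contiguous blocks of
    size ceil(n/k) or floor(n/k)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("cannot have more folds than rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_row = np.empty(n, dtype=np.int64)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    start = 0
    for fold, size in enumerate(sizes):
        fold_of_row[perm[start : start + size]] = fold
        start += size
    return FoldAssignment(fold_of_row=fold_of_row, k=k, seed=seed)


def stratified_k_fold_indices(data: Dataset, k: int, seed: int) -> FoldAssignment:
    """Class-stratified variant: per-class shuffled rows are dealt
    cyclically across folds, keeping fold sizes within one row."""
    n = data.n
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("cannot have more folds than rows")
    rng = np.random.default_rng(seed)
    labels = data.class_values.to_numpy(dtype=object)
    fold_of_row = np.empty(n, dtype=np.int64)
    cursor = 0
    for label in sorted(set(labels)):
        rows = np.nonzero(labels == label)[0]
        rng.shuffle(rows)
        for row in rows:
            fold_of_row[row] = cursor % k
            cursor += 1
    return FoldAssignment(fold_of_row=fold_of_row, k=k, seed=seed)


def confusion_matrix(
    actual: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Count actual-vs-predicted label pairs over an ordered label set."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    labels = tuple(labels)
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside the declared label set: {a!r}/{p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def accuracy(m: ConfusionMatrix) -> float:
    """Trace over total."""
    if m.total == 0:
        raise ValueError("accuracy of an empty confusion matrix is undefined")
    return m.trace / m.total


def matthews_cc(m: ConfusionMatrix) -> float:
    """Matthews correlation coefficient (multiclass R_k generalisation).

    ``(c*s - sum p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    with c = trace, s = total, t = row sums, p = column sums.  A zero
    denominator yields 0 by convention.
    """
    if m.total == 0:
        raise ValueError("MCC of an empty confusion matrix is undefined")
    c = float(m.trace)
    s = float(m.total)
    t = m.counts.sum(axis=1).astype(float)  # actual-class counts
    p = m.counts.sum(axis=0).astype(float)  # predicted-class counts
    numerator = c * s - float(p @ t)
    denominator = math.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if denominator == 0.0:
        return 0.0
    return numerator / denominator


def collapsed_precision(
    m: ConfusionMatrix, positive_labels: Sequence[str]
) -> float:
    """Precision after collapsing the matrix to positive-vs-rest 2x2.

    Cells are summed over (actual in P) x (predicted in P); the result is
    TP / (TP + FP), 0 by convention when nothing was predicted positive.
    """
    positives = set(positive_labels)
    if not positives:
        raise ValueError("positive label set must be non-empty")
    if not positives < set(m.labels):
        raise ValueError("positive labels must be a proper subset of the labels")
    pos_idx = [i for i, label in enumerate(m.labels) if label in positives]
    neg_idx = [i for i, label in enumerate(m.labels) if label not in positives]
    tp = int(m.counts[np.ix_(pos_idx, pos_idx)].sum())
    fp = int(m.counts[np.ix_(neg_idx, pos_idx)].sum())
    if tp + fp == 0:
        return 0.0
    return tp / (tp + fp)


def evaluate_holdout(
    train: Dataset,
    test: Dataset,
    criterion: CriterionKind,
    prune: bool = False,
    max_depth: int | None = None,
    positive_labels: Sequence[str] | None = None,
) -> tuple[DecisionTree, EvaluationReport]:
    """Train on *train*, predict *test*, and report pooled metrics."""
    start = time.perf_counter()
    tree = build_tree(train, criterion, prune=prune, max_depth=max_depth)
    actual = list(test.class_values)
    predicted = predict_dataset(tree, test)
    labels = sorted(set(train.class_counts()) | set(actual) | set(predicted))
    matrix = confusion_matrix(actual, predicted, labels)
    elapsed = time.perf_counter() - start
    report = EvaluationReport(
        matrix=matrix,
        accuracy=accuracy(matrix),
        mcc=matthews_cc(matrix),
        precision_collapsed=(
            collapsed_precision(matrix, positive_labels)
            if positive_labels
            else None
        ),
        generation_time=elapsed,
    )
    return tree, report


def cross_validate(
    data: Dataset,
    criterion: CriterionKind,
    k: int,
    seed: int,
    prune: bool = False,
    max_depth: int | None = None,
    stratified: bool = False,
    positive_labels: Sequence[str] | None = None,
) -> EvaluationReport:
    """k-fold cross-validation with a pooled confusion matrix.

    Each fold is predicted by a tree trained on the other k-1 folds; the
    per-fold predictions are pooled into one confusion matrix from which
    accuracy and MCC are computed.  Every row is predicted exactly once.
    """
    counts = data.class_counts()
    if any(c == 0 for c in counts.values()):
        raise ValueError("every class must be present in at least one row")
    folds = (
        stratified_k_fold_indices(data, k, seed)
        if stratified
        else k_fold_indices(data.n, k, seed)
    )
    start = time.perf_counter()
    actual: list[str] = []
    predicted: list[str] = []
    for fold in range(k):
        test_rows = folds.rows_in_fold(fold)
        train_rows = np.nonzero(folds.fold_of_row != fold)[0]
        tree = build_tree(
            data.subset(train_rows.tolist()),
            criterion,
            prune=prune,
            max_depth=max_depth,
        )
        held_out = data.subset(test_rows.tolist())
        actual.extend(held_out.class_values)
        predicted.extend(predict_dataset(tree, held_out))
    labels = sorted(set(counts) | set(predicted))
    matrix = confusion_matrix(actual, predicted, labels)
    elapsed = time.perf_counter() - start
    return EvaluationReport(
        matrix=matrix,
        accuracy=accuracy(matrix),
        mcc=matthews_cc(matrix),
        precision_collapsed=(
            collapsed_precision(matrix, positive_labels)
            if positive_labels
            else None
        ),
        generation_time=elapsed,
    )
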