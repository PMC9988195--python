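"""Independent brute-force oracles used to cross-check the split search.

Everything here is deliberately written from first principles -- plain
Python loops over row lists, Counter-based impurity formulas -- and never
calls into the package's own candidate enumeration, so a bug in the
implementation cannot hide in its oracle.
"""

from __future__ import annotations

import math
from collections import Counter

from dtgraph.tabular_io import CATEGORICAL, NUMERICAL, Dataset


def _gini(labels: list[str]) -> float:
    n = len(labels)
    return 1.0 - sum((c / n) ** 2 for c in Counter(labels).values())


def _entropy(labels: list[str]) -> float:
    n = len(labels)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(labels).values()
    )


def score_partition(
    all_labels: list[str],
    left: list[str],
    right: list[str],
    criterion: str,
) -> float:
    """Criterion score of one binary partition, from the raw formulas."""
    n = len(all_labels)
    wl, wr = len(left) / n, len(right) / n
    if criterion == "gini":
        return _gini(all_labels) - wl * _gini(left) - wr * _gini(right)
    gain = _entropy(all_labels) - wl * _entropy(left) - wr * _entropy(right)
    if criterion == "information_gain":
        return gain
    split_info = 0.0
    for w in (wl, wr):
        if w > 0:
            split_info -= w * math.log2(w)
    if split_info == 0.0:
        return 0.0
    return gain / split_info


def _feature_rows(data: Dataset, feature: str) -> list[tuple[object, str]]:
    values = data.column(feature)
    labels = data.class_values
    mask = values.notna()
    return [
        (v, str(y)) for v, y, ok in zip(values, labels, mask) if ok
    ]


def candidate_conditions(data: Dataset, feature: str) -> list[tuple[str, object]]:
    """Every admissible condition on one feature: ("numeric", threshold)
    or ("categorical", category)."""
    rows = _feature_rows(data, feature)
    kind = data.schema_for(feature).kind
    conditions: list[tuple[str, object]] = []
    if kind == NUMERICAL:
        distinct = sorted({float(v) for v, _ in rows})
        for a, b in zip(distinct, distinct[1:]):
            conditions.append(("numeric", (a + b) / 2.0))
    else:
        for category in sorted({str(v) for v, _ in rows}):
            conditions.append(("categorical", category))
    admissible = []
    for kind_tag, value in conditions:
        left, right = split_labels(rows, kind_tag, value)
        if left and right:
            admissible.append((kind_tag, value))
    return admissible


def split_labels(
    rows: list[tuple[object, str]], kind_tag: str, value: object
) -> tuple[list[str], list[str]]:
    if kind_tag == "numeric":
        left = [y for v, y in rows if float(v) <= value]
        right = [y for v, y in rows if float(v) > value]
    else:
        left = [y for v, y in rows if str(v) == value]
        right = [y for v, y in rows if str(v) != value]
    return left, right


def condition_score(
    data: Dataset, feature: str, kind_tag: str, value: object, criterion: str
) -> float:
    rows = _feature_rows(data, feature)
    left, right = split_labels(rows, kind_tag, value)
    return score_partition([y for _, y in rows], left, right, criterion)


def brute_force_best_split(data: Dataset, criterion: str):
    """Exhaustively enumerate every admissible binary partition induced by
    thresholds and category equalities, returning the winner under the same
    deterministic tie order (earlier feature, then ascending condition).

    Returns (feature, kind_tag, value, score) or None.
    """
    best = None
    for feature in data.feature_names:
        for kind_tag, value in candidate_conditions(data, feature):
            score = condition_score(data, feature, kind_tag, value, criterion)
            if best is None or score > best[3]:
                best = (feature, kind_tag, value, score)
    if best is None or best[3] <= 0.0:
        return None
    return best
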