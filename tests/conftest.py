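"""Shared fixtures and dataset generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dtgraph.tabular_io import Dataset
from dtgraph.tree import DecisionNode, DecisionTree


@pytest.fixture
def xy_dataset() -> Dataset:
    """Four rows, one numeric feature, perfectly separable at x <= 2.5."""
    return Dataset.from_dict(
        {"x": [1, 2, 3, 4], "y": ["A", "A", "B", "B"]}, class_label="y"
    )


@pytest.fixture
def pure_dataset() -> Dataset:
    return Dataset.from_dict(
        {"x": [1, 2, 3], "y": ["A", "A", "A"]}, class_label="y"
    )


def features_used(tree: DecisionTree) -> set[str]:
    """The set of features tested by the tree's decision nodes."""
    seen: set[str] = set()

    def walk(node):
        if isinstance(node, DecisionNode):
            seen.add(node.feature)
            walk(node.true_child)
            walk(node.false_child)

    walk(tree.root)
    return seen


def random_dataset(
    rng: np.random.Generator,
    max_rows: int = 30,
    max_features: int = 3,
    with_missing: bool = False,
    conflict_free: bool = False,
) -> Dataset:
    """A small random mixed-type dataset for oracle and property tests.

    Numeric features draw from a coarse integer grid so that ties between
    candidate thresholds and between features actually occur.  With
    ``conflict_free`` a strictly distinct numeric column is added so no
    two rows share a feature vector with different labels.
    """
    n = int(rng.integers(2, max_rows + 1))
    n_features = int(rng.integers(1, max_features + 1))
    columns: dict[str, list] = {}
    for j in range(n_features):
        if rng.random() < 0.5:
            values = rng.integers(0, 5, size=n).astype(float).tolist()
        else:
            values = rng.choice(["a", "b", "c"], size=n).tolist()
        if with_missing and n > 3:
            for i in np.nonzero(rng.random(n) < 0.15)[0]:
                values[i] = None
        columns[f"f{j}"] = values
    if conflict_free:
        jitter = rng.permutation(n).astype(float) + rng.uniform(0, 0.25, n)
        columns["uid"] = jitter.tolist()
    n_classes = int(rng.integers(2, 4))
    columns["y"] = rng.choice(["X", "Y", "Z"][:n_classes], size=n).tolist()
    return Dataset.from_dict(columns, class_label="y")
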