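"""Typed tabular input for decision-tree induction.

This module turns the two accepted input forms -- RFC-4180-style CSV files
and JSON "node buckets" (homogeneous, unconnected property-graph nodes,
one node per instance) -- into a :class:`Dataset`: an ordered, typed,
row-oriented table with exactly one designated class-label column.

Column types are inferred rather than declared: a column is *numerical*
when every non-missing cell parses as a finite real number, otherwise it
is *categorical*.  The class-label column is always categorical, even when
its values look numeric -- clinical outcome labels such as ``0``/``1`` are
codes, not quantities.  The empty string and the literal ``NA`` both mark
a missing cell.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORICAL = "categorical"
NUMERICAL = "numerical"

_MISSING_TOKENS = frozenset({"", "NA"})
# Deterministic, locale-independent numeric dialect: optional sign, integer
# or decimal notation, optional scientific exponent.
_NUMERIC_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")


class DatasetError(ValueError):
    """Raised for malformed tabular input or schema violations."""


def is_missing_cell(cell: object) -> bool:
    """True when *cell* encodes a missing value (None, NaN, "" or "NA")."""
    if cell is None:
        return True
    if isinstance(cell, float):
        return math.isnan(cell)
    if isinstance(cell, str):
        return cell.strip() in _MISSING_TOKENS
    return False


def parse_numeric(cell: str) -> float | None:
    """Parse *cell* as a finite real, or return None if it does not conform."""
    text = cell.strip()
    if not _NUMERIC_RE.fullmatch(text):
        return None
    value = float(text)
    return value if math.isfinite(value) else None


@dataclass(frozen=True)
class ColumnSchema:
    """Name, inferred kind and class-label flag of one column."""

    name: str
    kind: str
    is_class_label: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, NUMERICAL):
            raise DatasetError(f"unknown column kind: {self.kind!r}")
        if self.is_class_label and self.kind != CATEGORICAL:
            raise DatasetError("the class-label column must be categorical")


def infer_column_types(
    raw_columns: Mapping[str, Sequence[str | None]], class_label: str
) -> list[ColumnSchema]:
    """Infer one :class:`ColumnSchema` per column of text cells.

    A column is numerical iff every non-missing cell parses as a finite
    real; the class-label column is forced categorical regardless of its
    content.  Column order follows the mapping's iteration order.
    """
    if class_label not in raw_columns:
        raise DatasetError(f"class label {class_label!r} is not a column")
    schema = []
    for name, cells in raw_columns.items():
        non_missing = [c for c in cells if not is_missing_cell(c)]
        if not non_missing:
            raise DatasetError(f"column {name!r} has no non-missing cells")
        if name == class_label:
            schema.append(ColumnSchema(name, CATEGORICAL, is_class_label=True))
            continue
        numeric = all(parse_numeric(str(c)) is not None for c in non_missing)
        schema.append(ColumnSchema(name, NUMERICAL if numeric else CATEGORICAL))
    return schema


class Dataset:
    """An immutable typed table with one class-label column.

    Backed by a :class:`pandas.DataFrame`: numerical columns are float64
    with NaN marking missing cells; categorical columns hold strings with
    None marking missing cells.  The class-label column is categorical and
    never missing.  Row order is meaningful and preserved.
    """

    def __init__(self, frame: pd.DataFrame, schema: Sequence[ColumnSchema]):
        schema = tuple(schema)
        names = [c.name for c in schema]
        if list(frame.columns) != names:
            raise DatasetError("frame columns do not match schema order")
        if len(names) != len(set(names)):
            raise DatasetError("duplicate column names")
        class_cols = [c for c in schema if c.is_class_label]
        if len(class_cols) != 1:
            raise DatasetError("exactly one class-label column is required")
        frame = frame.reset_index(drop=True)
        for col in schema:
            if col.kind == NUMERICAL:
                frame[col.name] = frame[col.name].astype(np.float64)
            else:
                frame[col.name] = frame[col.name].astype(object)
        label_col = frame[class_cols[0].name]
        if label_col.isna().any():
            raise DatasetError("missing value in the class-label column")
        self._frame = frame
        self._schema = schema
        self._class_label = class_cols[0].name

    # -- construction -----------------------------------------------------

    @classmethod
    def from_text_columns(
        cls, raw_columns: Mapping[str, Sequence[str | None]], class_label: str
    ) -> "Dataset":
        """Build a Dataset from columns of text cells with type inference."""
        schema = infer_column_types(raw_columns, class_label)
        lengths = {len(v) for v in raw_columns.values()}
        if len(lengths) > 1:
            raise DatasetError("columns have unequal lengths")
        data: dict[str, object] = {}
        for col in schema:
            cells = raw_columns[col.name]
            if col.kind == NUMERICAL:
                data[col.name] = np.array(
                    [
                        np.nan if is_missing_cell(c) else parse_numeric(str(c))
                        for c in cells
                    ],
                    dtype=np.float64,
                )
            else:
                data[col.name] = np.array(
                    [None if is_missing_cell(c) else str(c) for c in cells],
                    dtype=object,
                )
        return cls(pd.DataFrame(data, columns=[c.name for c in schema]), schema)

    @classmethod
    def from_dict(
        cls, data: Mapping[str, Sequence[object]], class_label: str
    ) -> "Dataset":
        """Build a Dataset from python values (convenience for small tables)."""
        text = {
            name: [None if is_missing_cell(v) else str(v) for v in cells]
            for name, cells in data.items()
        }
        return cls.from_text_columns(text, class_label)

    # -- basic accessors ---------------------------------------------------

    @property
    def schema(self) -> tuple[ColumnSchema, ...]:
        return self._schema

    @property
    def frame(self) -> pd.DataFrame:
        """The backing DataFrame (treat as read-only)."""
        return self._frame

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def class_label(self) -> str:
        return self._class_label

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self._schema if not c.is_class_label)

    @property
    def class_values(self) -> pd.Series:
        return self._frame[self._class_label]

    def class_counts(self) -> dict[str, int]:
        """Class-label counts, keyed by label, in lexicographic label order."""
        counts = self.class_values.value_counts()
        return {label: int(counts[label]) for label in sorted(counts.index)}

    def schema_for(self, name: str) -> ColumnSchema:
        for col in self._schema:
            if col.name == name:
                return col
        raise DatasetError(f"unknown column {name!r}")

    def column(self, name: str) -> pd.Series:
        self.schema_for(name)
        return self._frame[name]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """A new Dataset holding the given rows (positional), in given order."""
        return Dataset(self._frame.iloc[list(indices)], self._schema)

    def rows(self) -> Iterator[dict[str, object]]:
        """Iterate rows as plain dicts; missing cells become None."""
        for record in self._frame.itertuples(index=False, name=None):
            yield {
                col.name: (None if is_missing_cell(v) else v)
                for col, v in zip(self._schema, record)
            }

    def has_missing_features(self) -> bool:
        """True when any non-class cell is missing."""
        for name in self.feature_names:
            if self._frame[name].isna().any():
                return True
        return False

    # -- output ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as UTF-8 comma-separated text; missing cells become ""."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([c.name for c in self._schema])
            for record in self._frame.itertuples(index=False, name=None):
                out = []
                for col, v in zip(self._schema, record):
                    if is_missing_cell(v):
                        out.append("")
                    elif col.kind == NUMERICAL:
                        out.append(repr(float(v)))
                    else:
                        out.append(str(v))
                writer.writerow(out)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"Dataset(n={self.n}, columns={len(self._schema)}, "
            f"class_label={self._class_label!r})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._schema == other._schema and self._frame.equals(other._frame)


def read_csv_dataset(path: str | Path, class_label: str) -> Dataset:
    """Read a header-row CSV file into a typed :class:`Dataset`."""
    p = Path(path)
    if not p.exists():
        raise DatasetError(f"no such file: {p}")
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError(f"{p}: empty file") from None
        rows = list(reader)
    if class_label not in header:
        raise DatasetError(f"class label {class_label!r} absent from header")
    if len(header) != len(set(header)):
        raise DatasetError("duplicate header names")
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise DatasetError(
                f"row {i + 2} has {len(row)} cells, header has {len(header)}"
            )
    columns = {name: [row[j] for row in rows] for j, name in enumerate(header)}
    if any(is_missing_cell(c) for c in columns[class_label]):
        raise DatasetError("missing value in the class-label column")
    return Dataset.from_text_columns(columns, class_label)


def load_node_bucket(path: str | Path, class_label: str) -> Dataset:
    """Read a JSON bucket of homogeneous unconnected nodes into a Dataset.

    The file holds a JSON array of ``{"id": ..., "properties": {...}}``
    objects; every node must carry the same property keys (homogeneity)
    including *class_label*.  One Dataset row is produced per node.
    """
    p = Path(path)
    if not p.exists():
        raise DatasetError(f"no such file: {p}")
    with open(p, encoding="utf-8") as fh:
        payload = json.load(fh)
    return node_bucket_to_dataset(payload, class_label)


def node_bucket_to_dataset(payload: object, class_label: str) -> Dataset:
    """Convert an in-memory node-bucket payload into a Dataset."""
    if not isinstance(payload, list):
        raise DatasetError("node bucket must be a JSON array of nodes")
    if not payload:
        raise DatasetError("empty node bucket: no rows to infer types from")
    first_props = _node_properties(payload[0])
    keys = list(first_props)
    if class_label not in keys:
        raise DatasetError(f"nodes do not carry class property {class_label!r}")
    columns: dict[str, list[str | None]] = {k: [] for k in keys}
    for node in payload:
        props = _node_properties(node)
        if set(props) != set(keys):
            raise DatasetError("heterogeneous property keys across nodes")
        for k in keys:
            columns[k].append(_property_cell(props[k]))
    if any(c is None for c in columns[class_label]):
        raise DatasetError("missing value in the class-label property")
    return Dataset.from_text_columns(columns, class_label)


def _node_properties(node: object) -> Mapping[str, object]:
    if (
        not isinstance(node, dict)
        or "properties" not in node
        or not isinstance(node["properties"], dict)
    ):
        raise DatasetError(
            'each node must be an object {"id": ..., "properties": {...}}'
        )
    return node["properties"]


def _property_cell(value: object) -> str | None:
    if value is None:
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return str(value)


def split_train_test(
    data: Dataset, train_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Randomly partition rows into disjoint train and test Datasets.

    The train size is ``round(train_fraction * n)`` with half-up rounding;
    the same seed always yields the same partition.  Row order inside each
    part follows the original dataset.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must lie strictly between 0 and 1")
    if data.n < 2:
        raise DatasetError("need at least 2 rows to split")
    train_size = int(math.floor(train_fraction * data.n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    train_idx = np.sort(perm[:train_size])
    test_idx = np.sort(perm[train_size:])
    return data.subset(train_idx.tolist()), data.subset(test_idx.tolist())
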