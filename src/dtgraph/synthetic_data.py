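"""Seeded clinical-style synthetic fixtures.

This module generates tabular datasets that emulate the *shapes* of
typical clinical classification problems -- instance counts, feature
counts and mixes, class counts and imbalance, missingness -- without any
external download.  Feature values are drawn from simple parametric
families (uniform, normal, lognormal, multinomial); unless a planted rule
is given, features are independent of the label apart from an optional
per-class mean shift on numeric columns, so fixtures exercise the
induction machinery rather than mimic real biology.

Planted-rule datasets label each row by a deterministic predicate over at
most two features (plus optional label noise), giving recovery tests a
known ground truth: a correct learner must find exactly those features.

:func:`balanced_subsample` handles class imbalance by downsampling every
class, without replacement, to the minority-class count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tabular_io import CATEGORICAL, NUMERICAL, ColumnSchema, Dataset, DatasetError

Distribution = tuple
Rule = Callable[[Mapping[str, object]], str]


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: name, kind and sampling distribution.

    Supported distributions:
      ("uniform", lo, hi)                  -- numerical
      ("uniform_gap", lo, hi, glo, ghi)    -- uniform on [lo,hi] minus the
                                              open gap (glo, ghi); leaves a
                                              margin around a planted
                                              threshold
      ("normal", mu, sigma)                -- numerical
      ("lognormal", mu, sigma)             -- numerical
      ("choice", values, probs)            -- categorical
    """

    name: str
    kind: str
    distribution: Distribution

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        family = self.distribution[0]
        if family == "uniform":
            _, lo, hi = self.distribution
            return rng.uniform(lo, hi, size=n)
        if family == "uniform_gap":
            _, lo, hi, glo, ghi = self.distribution
            if not lo <= glo < ghi <= hi:
                raise DatasetError("uniform_gap gap must lie inside the range")
            width = (hi - lo) - (ghi - glo)
            u = rng.uniform(0.0, width, size=n)
            values = lo + u
            return np.where(values < glo, values, values + (ghi - glo))
        if family == "normal":
            _, mu, sigma = self.distribution
            return rng.normal(mu, sigma, size=n)
        if family == "lognormal":
            _, mu, sigma = self.distribution
            return rng.lognormal(mu, sigma, size=n)
        if family == "choice":
            _, values, probs = self.distribution
            return rng.choice(np.array(values, dtype=object), size=n, p=probs)
        raise DatasetError(f"unknown distribution family {family!r}")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset.

    Class sizes come either from exact ``class_counts`` or from
    ``class_proportions`` resolved by deterministic largest-remainder
    rounding; with a ``planted_rule`` the label is instead computed from
    the features (optionally flipped at ``label_noise`` rate).
    ``class_shift`` adds ``shift * class_index`` to numeric features,
    giving label-dependent signal without a planted rule.  ``imbalance``
    is an informational tag (low / medium / high).
    """

    n_instances: int
    features: Sequence[FeatureSpec]
    class_label: str
    class_values: Sequence[str]
    class_counts: Sequence[int] | None = None
    class_proportions: Sequence[float] | None = None
    imbalance: str | None = None
    missing_rate: float = 0.0
    planted_rule: Rule | None = None
    label_noise: float = 0.0
    class_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise DatasetError("n_instances must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DatasetError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.label_noise < 1.0:
            raise DatasetError("label_noise must lie in [0, 1)")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)) or self.class_label in names:
            raise DatasetError("feature names must be unique and not the label")
        if self.planted_rule is None:
            if (self.class_counts is None) == (self.class_proportions is None):
                raise DatasetError(
                    "give exactly one of class_counts or class_proportions"
                )
            if self.class_counts is not None:
                if len(self.class_counts) != len(self.class_values):
                    raise DatasetError("one count per class value required")
                if sum(self.class_counts) != self.n_instances:
                    raise DatasetError("class counts must sum to n_instances")
            else:
                if len(self.class_proportions) != len(self.class_values):
                    raise DatasetError("one proportion per class value required")
                if abs(sum(self.class_proportions) - 1.0) > 1e-9:
                    raise DatasetError("class proportions must sum to 1")


def largest_remainder(proportions: Sequence[float], n: int) -> list[int]:
    """Apportion n into integer counts matching proportions: floor the
    quotas, then hand remaining units to the largest fractional parts
    (ties to the earlier index)."""
    quotas = [p * n for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _resolve_counts(spec: FixtureSpec) -> list[int]:
    if spec.class_counts is not None:
        return list(spec.class_counts)
    return largest_remainder(spec.class_proportions, spec.n_instances)


def _build_dataset(
    spec: FixtureSpec,
    feature_columns: dict[str, np.ndarray],
    labels: np.ndarray,
) -> Dataset:
    schema = [
        ColumnSchema(f.name, f.kind) for f in spec.features
    ] + [ColumnSchema(spec.class_label, CATEGORICAL, is_class_label=True)]
    data = dict(feature_columns)
    data[spec.class_label] = labels
    frame = pd.DataFrame(data, columns=[c.name for c in schema])
    return Dataset(frame, schema)


def _sample_features(
    spec: FixtureSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    columns = {}
    for feature in spec.features:
        values = feature.sample(spec.n_instances, rng)
        if feature.kind == NUMERICAL:
            values = values.astype(np.float64)
        else:
            values = values.astype(object)
        columns[feature.name] = values
    return columns


def _apply_missingness(
    spec: FixtureSpec, columns: dict[str, np.ndarray], rng: np.random.Generator
) -> None:
    if spec.missing_rate == 0.0:
        return
    for feature in spec.features:
        mask = rng.random(spec.n_instances) < spec.missing_rate
        col = columns[feature.name]
        if feature.kind == NUMERICAL:
            col[mask] = np.nan
        else:
            col[mask] = None


def generate_fixture(spec: FixtureSpec) -> Dataset:
    """Generate the dataset described by *spec* (seeded, reproducible)."""
    if spec.planted_rule is not None:
        return generate_planted_rule_dataset(spec)
    rng = np.random.default_rng(spec.seed)
    counts = _resolve_counts(spec)
    labels = np.array(
        [
            label
            for label, count in zip(spec.class_values, counts)
            for _ in range(count)
        ],
        dtype=object,
    )
    rng.shuffle(labels)
    columns = _sample_features(spec, rng)
    if spec.class_shift:
        class_index = {v: i for i, v in enumerate(spec.class_values)}
        shift = np.array([class_index[l] for l in labels], dtype=np.float64)
        for feature in spec.features:
            if feature.kind == NUMERICAL:
                columns[feature.name] = (
                    columns[feature.name] + spec.class_shift * shift
                )
    _apply_missingness(spec, columns, rng)
    return _build_dataset(spec, columns, labels)


def generate_planted_rule_dataset(spec: FixtureSpec) -> Dataset:
    """Generate a dataset whose label follows the planted rule.

    Features are sampled independently; each row's label is the rule's
    output, flipped to a uniformly random *other* class value at the
    ``label_noise`` rate.
    """
    if spec.planted_rule is None:
        raise DatasetError("spec has no planted rule")
    rng = np.random.default_rng(spec.seed)
    columns = _sample_features(spec, rng)
    class_values = list(spec.class_values)
    labels = np.empty(spec.n_instances, dtype=object)
    for i in range(spec.n_instances):
        row = {name: columns[name][i] for name in columns}
        label = str(spec.planted_rule(row))
        if label not in class_values:
            raise DatasetError(f"rule produced unknown label {label!r}")
        labels[i] = label
    if spec.label_noise > 0.0:
        flip = rng.random(spec.n_instances) < spec.label_noise
        for i in np.nonzero(flip)[0]:
            others = [v for v in class_values if v != labels[i]]
            labels[i] = others[rng.integers(len(others))]
    _apply_missingness(spec, columns, rng)
    return _build_dataset(spec, columns, labels)


def balanced_subsample(data: Dataset, seed: int) -> Dataset:
    """Downsample every class, without replacement, to the minority count.

    The output holds ``k_classes * min_count`` rows in a seeded shuffled
    order; already balanced input keeps its class counts.
    """
    counts = data.class_counts()
    if len(counts) < 2:
        raise DatasetError("balanced subsampling needs at least 2 classes")
    if any(c == 0 for c in counts.values()):
        raise DatasetError("every class needs at least one row")
    minimum = min(counts.values())
    rng = np.random.default_rng(seed)
    labels = data.class_values.to_numpy(dtype=object)
    chosen: list[np.ndarray] = []
    for label in sorted(counts):
        rows = np.nonzero(labels == label)[0]
        chosen.append(rng.choice(rows, size=minimum, replace=False))
    picked = np.concatenate(chosen)
    rng.shuffle(picked)
    return data.subset(picked.tolist())


# -- planted-rule convenience ------------------------------------------------


def bmi_bp_rule(row: Mapping[str, object]) -> str:
    """Label "1" iff bmi > 30 and highBP == "yes", else "0"."""
    return "1" if float(row["bmi"]) > 30.0 and row["highBP"] == "yes" else "0"


def planted_bmi_bp_spec(
    n_instances: int = 200,
    seed: int = 0,
    label_noise: float = 0.0,
    missing_rate: float = 0.0,
) -> FixtureSpec:
    """A two-feature planted rule: class 1 iff bmi > 30 and highBP = yes.

    bmi takes the midpoints of four clinical BMI bands (normal,
    overweight, obese I, obese II), so at the default size every band is
    well populated: the boundary between 27 and 32 is wide, its learned
    threshold cannot drift past a neighbouring band by chance, and the
    rule is recoverable exactly from finite samples.  Hypertension is
    prevalent (70%), keeping the obese bands visibly mixed so no spurious
    pure block forms above the boundary.  Three label-independent noise
    features are included.
    """
    return FixtureSpec(
        n_instances=n_instances,
        features=[
            FeatureSpec(
                "bmi",
                NUMERICAL,
                ("choice", (22.0, 27.0, 32.0, 37.0), (0.25, 0.3, 0.25, 0.2)),
            ),
            FeatureSpec("highBP", CATEGORICAL, ("choice", ("no", "yes"), (0.3, 0.7))),
            FeatureSpec("age", NUMERICAL, ("uniform", 18.0, 90.0)),
            FeatureSpec("cholesterol", NUMERICAL, ("normal", 200.0, 30.0)),
            FeatureSpec(
                "smoker", CATEGORICAL, ("choice", ("no", "yes"), (0.7, 0.3))
            ),
        ],
        class_label="outcome",
        class_values=("0", "1"),
        planted_rule=bmi_bp_rule,
        label_noise=label_noise,
        missing_rate=missing_rate,
        seed=seed,
    )


# -- shape presets ----------------------------------------------------------


def _heart_failure_spec(seed: int) -> FixtureSpec:
    """299 instances, 13 columns (7 continuous + 5 binary + binary label),
    medium imbalance (96 deaths vs 203 survivors)."""
    binary = ("choice", ("0", "1"), (0.6, 0.4))
    return FixtureSpec(
        n_instances=299,
        features=[
            FeatureSpec("age", NUMERICAL, ("uniform", 40.0, 95.0)),
            FeatureSpec("creatinine_phosphokinase", NUMERICAL, ("lognormal", 5.5, 1.0)),
            FeatureSpec("ejection_fraction", NUMERICAL, ("uniform", 14.0, 80.0)),
            FeatureSpec("platelets", NUMERICAL, ("normal", 263000.0, 97000.0)),
            FeatureSpec("serum_creatinine", NUMERICAL, ("lognormal", 0.2, 0.4)),
            FeatureSpec("serum_sodium", NUMERICAL, ("normal", 136.0, 4.4)),
            FeatureSpec("time", NUMERICAL, ("uniform", 4.0, 285.0)),
            FeatureSpec("anaemia", CATEGORICAL, binary),
            FeatureSpec("diabetes", CATEGORICAL, binary),
            FeatureSpec("high_blood_pressure", CATEGORICAL, binary),
            FeatureSpec("sex", CATEGORICAL, ("choice", ("0", "1"), (0.35, 0.65))),
            FeatureSpec("smoking", CATEGORICAL, ("choice", ("0", "1"), (0.68, 0.32))),
        ],
        class_label="DEATH_EVENT",
        class_values=("0", "1"),
        class_counts=(203, 96),
        imbalance="medium",
        class_shift=0.4,
        seed=seed,
    )


def _ibd_metaproteome_spec(seed: int) -> FixtureSpec:
    """48 instances, 51 columns (the 50 most abundant metaprotein
    abundances + 3-class label), low imbalance (20 C / 13 CD / 15 UC)."""
    features = [
        FeatureSpec(f"metaprotein_{i:02d}", NUMERICAL, ("lognormal", 3.0, 1.2))
        for i in range(1, 51)
    ]
    return FixtureSpec(
        n_instances=48,
        features=features,
        class_label="patient_type",
        class_values=("C", "CD", "UC"),
        class_counts=(20, 13, 15),
        imbalance="low",
        class_shift=3.0,
        seed=seed,
    )


def _flu_covid_spec(seed: int) -> FixtureSpec:
    """1,485 instances, 12 columns (2 continuous + 9 categorical + binary
    label), high imbalance (1072 H1N1 vs 413 COVID-19), sparse cells."""
    yn = ("choice", ("no", "yes"), (0.5, 0.5))
    return FixtureSpec(
        n_instances=1485,
        features=[
            FeatureSpec("age", NUMERICAL, ("uniform", 1.0, 95.0)),
            FeatureSpec("temperature", NUMERICAL, ("normal", 38.0, 0.9)),
            FeatureSpec("cough", CATEGORICAL, yn),
            FeatureSpec("fever", CATEGORICAL, ("choice", ("no", "yes"), (0.3, 0.7))),
            FeatureSpec("sore_throat", CATEGORICAL, yn),
            FeatureSpec("headache", CATEGORICAL, yn),
            FeatureSpec("dyspnea", CATEGORICAL, ("choice", ("no", "yes"), (0.7, 0.3))),
            FeatureSpec("fatigue", CATEGORICAL, yn),
            FeatureSpec("diarrhea", CATEGORICAL, ("choice", ("no", "yes"), (0.8, 0.2))),
            FeatureSpec("sex", CATEGORICAL, ("choice", ("F", "M"), (0.5, 0.5))),
            FeatureSpec(
                "contact_history",
                CATEGORICAL,
                ("choice", ("no", "yes", "unknown"), (0.5, 0.3, 0.2)),
            ),
        ],
        class_label="diagnosis",
        class_values=("H1N1", "COVID19"),
        class_counts=(1072, 413),
        imbalance="high",
        missing_rate=0.05,
        class_shift=0.5,
        seed=seed,
    )


def _diabetes_spec(seed: int) -> FixtureSpec:
    """253,680 instances, 22 columns (2 continuous + 19 categorical +
    3-class label), high imbalance (213,703 / 4,631 / 35,346)."""
    binary = ("choice", ("0", "1"), (0.5, 0.5))
    features = [
        FeatureSpec("bmi", NUMERICAL, ("normal", 28.4, 6.6)),
        FeatureSpec("mental_health_days", NUMERICAL, ("lognormal", 0.5, 1.2)),
        FeatureSpec("high_bp", CATEGORICAL, ("choice", ("0", "1"), (0.57, 0.43))),
        FeatureSpec("high_chol", CATEGORICAL, ("choice", ("0", "1"), (0.58, 0.42))),
        FeatureSpec("chol_check", CATEGORICAL, ("choice", ("0", "1"), (0.04, 0.96))),
        FeatureSpec("smoker", CATEGORICAL, ("choice", ("0", "1"), (0.56, 0.44))),
        FeatureSpec("stroke", CATEGORICAL, ("choice", ("0", "1"), (0.96, 0.04))),
        FeatureSpec("heart_disease", CATEGORICAL, ("choice", ("0", "1"), (0.9, 0.1))),
        FeatureSpec("phys_activity", CATEGORICAL, ("choice", ("0", "1"), (0.24, 0.76))),
        FeatureSpec("fruits", CATEGORICAL, ("choice", ("0", "1"), (0.37, 0.63))),
        FeatureSpec("veggies", CATEGORICAL, ("choice", ("0", "1"), (0.19, 0.81))),
        FeatureSpec("heavy_alcohol", CATEGORICAL, ("choice", ("0", "1"), (0.94, 0.06))),
        FeatureSpec("any_healthcare", CATEGORICAL, ("choice", ("0", "1"), (0.05, 0.95))),
        FeatureSpec("no_doc_cost", CATEGORICAL, ("choice", ("0", "1"), (0.92, 0.08))),
        FeatureSpec(
            "general_health",
            CATEGORICAL,
            ("choice", ("1", "2", "3", "4", "5"), (0.18, 0.35, 0.3, 0.12, 0.05)),
        ),
        FeatureSpec("diff_walk", CATEGORICAL, ("choice", ("0", "1"), (0.83, 0.17))),
        FeatureSpec("sex", CATEGORICAL, binary),
        FeatureSpec(
            "age_band",
            CATEGORICAL,
            (
                "choice",
                tuple(str(i) for i in range(1, 14)),
                tuple([0.02, 0.03, 0.05, 0.06, 0.07, 0.08, 0.1, 0.12, 0.13, 0.12, 0.1, 0.07, 0.05]),
            ),
        ),
        FeatureSpec(
            "education",
            CATEGORICAL,
            ("choice", ("1", "2", "3", "4", "5", "6"), (0.01, 0.02, 0.04, 0.25, 0.28, 0.4)),
        ),
        FeatureSpec(
            "income",
            CATEGORICAL,
            (
                "choice",
                tuple(str(i) for i in range(1, 9)),
                tuple([0.04, 0.05, 0.06, 0.08, 0.1, 0.14, 0.17, 0.36]),
            ),
        ),
        FeatureSpec("phys_health_days", NUMERICAL, ("lognormal", 0.8, 1.3)),
    ]
    return FixtureSpec(
        n_instances=253680,
        features=features,
        class_label="diabetes_status",
        class_values=("0", "1", "2"),
        class_counts=(213703, 4631, 35346),
        imbalance="high",
        class_shift=1.5,
        seed=seed,
    )


_PRESETS: dict[str, Callable[[int], FixtureSpec]] = {
    "heart_failure": _heart_failure_spec,
    "ibd_metaproteome": _ibd_metaproteome_spec,
    "flu_covid": _flu_covid_spec,
    "diabetes": _diabetes_spec,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_spec(
    name: str, seed: int = 0, n_instances: int | None = None
) -> FixtureSpec:
    """A named fixture recipe; ``n_instances`` rescales the preset with
    class counts re-apportioned by largest remainder."""
    if name not in _PRESETS:
        raise DatasetError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    spec = _PRESETS[name](seed)
    if n_instances is not None and n_instances != spec.n_instances:
        proportions = [c / spec.n_instances for c in spec.class_counts]
        spec = replace(
            spec,
            n_instances=n_instances,
            class_counts=tuple(largest_remainder(proportions, n_instances)),
        )
    return spec
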