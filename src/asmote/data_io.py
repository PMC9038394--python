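"""Typed in-memory dataset, CSV reading/writing, and schema validation.

A :class:`Dataset` is the unit every stage consumes and produces: a numeric
feature matrix, a binary label vector, and per-column typing that says which
columns are continuous measurements and which are categorical codes.  The
bundled ``schemas/heart_uci.json`` reproduces the 13-feature UCI Heart
Disease layout (age, sex, cp, trestbps, chol, fbs, restecg, thalach, exang,
oldpeak, slope, ca, thal) with the target column ``num``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CategoryValueError,
    EmptyDatasetError,
    MissingTargetError,
    MissingValueError,
    NonNumericValueError,
    SchemaMismatchError,
    SingleClassError,
    TargetCardinalityError,
)

#: columns with at most this many distinct integer values are inferred categorical
CATEGORICAL_INFERENCE_MAX_LEVELS = 10


@dataclass(frozen=True)
class ColumnSpec:
    """Typing of one feature column.

    Parameters
    ----------
    name : str
        Column identifier as it appears in the CSV header.
    kind : {"continuous", "categorical"}
    categories : tuple of float, optional
        Admissible numeric codes, in order; required (>= 2 entries) for
        categorical columns and forbidden for continuous ones.
    """

    name: str
    kind: str
    categories: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaMismatchError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaMismatchError(
                    f"categorical column {self.name!r} needs >= 2 categories"
                )
            object.__setattr__(self, "categories", tuple(float(c) for c in self.categories))
        elif self.categories is not None:
            raise SchemaMismatchError(f"continuous column {self.name!r} must not list categories")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


@dataclass
class Dataset:
    """Feature matrix ``X``, binary labels ``y`` and per-column typing.

    ``positive_label`` / ``negative_label`` retain the original target values
    (e.g. ``"YES"``/``"NO"``) so files can be written back losslessly; ``y``
    itself is always 0/1 with 1 meaning "disease present".
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[ColumnSpec]
    positive_label: object = 1
    negative_label: object = 0
    target_name: str = "num"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def validate(self) -> None:
        if self.X.ndim != 2:
            raise EmptyDatasetError("feature matrix must be 2-D")
        if self.X.shape[0] == 0 or self.X.shape[1] == 0:
            raise EmptyDatasetError("dataset has no rows or no feature columns")
        if self.X.shape[0] != self.y.shape[0]:
            raise SchemaMismatchError("row count of X must equal length of y")
        if self.X.shape[1] != len(self.columns):
            raise SchemaMismatchError("column count of X must equal len(columns)")
        if not np.isfinite(self.X).all():
            raise MissingValueError("feature matrix contains NaN or infinite cells")
        if not np.isin(self.y, (0, 1)).all():
            raise TargetCardinalityError("labels must be 0/1")
        for j, col in enumerate(self.columns):
            if col.is_categorical:
                bad = ~np.isin(self.X[:, j], col.categories)
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise CategoryValueError(
                        f"value {self.X[i, j]!r} in column {col.name!r} (row {i}) "
                        f"is outside its declared categories {col.categories}"
                    )

    def copy(self) -> "Dataset":
        return replace(self, X=self.X.copy(), y=self.y.copy(), columns=list(self.columns))


@dataclass
class ClassSplit:
    """Minority/majority partition of a :class:`Dataset`.

    ``S_m`` holds the z minority rows, ``S_a`` the r majority rows; the index
    arrays map each back into the parent dataset.
    """

    S_m: np.ndarray
    S_a: np.ndarray
    minority_label: int
    columns: list[ColumnSpec] = field(default_factory=list)
    idx_m: np.ndarray | None = None
    idx_a: np.ndarray | None = None

    @property
    def z(self) -> int:
        return self.S_m.shape[0]

    @property
    def r(self) -> int:
        return self.S_a.shape[0]


# ---------------------------------------------------------------------------
# target handling
# ---------------------------------------------------------------------------

_POSITIVE_TOKENS = {"yes", "true", "present", "pos", "positive", "1"}


def _infer_positive(values: Sequence[object]) -> object:
    """Pick which of two target values means 'disease present'.

    YES/TRUE/PRESENT-style tokens win; otherwise the numerically (or
    lexicographically) larger value is positive, so 0/1 targets map to 1.
    """
    a, b = values
    for v in (a, b):
        if str(v).strip().lower() in _POSITIVE_TOKENS:
            return v
    try:
        return max((a, b), key=float)
    except (TypeError, ValueError):
        return max(a, b, key=str)


def _encode_target(raw: pd.Series, positive_label: object | None) -> tuple[np.ndarray, object, object]:
    if raw.isna().any():
        raise MissingValueError(f"target column {raw.name!r} has missing values")
    values = list(pd.unique(raw))
    if len(values) != 2:
        raise TargetCardinalityError(
            f"target column {raw.name!r} has {len(values)} distinct values; exactly 2 required"
        )
    if positive_label is not None:
        matches = [v for v in values if v == positive_label or str(v) == str(positive_label)]
        if not matches:
            raise TargetCardinalityError(
                f"positive label {positive_label!r} not among target values {values}"
            )
        pos = matches[0]
    else:
        pos = _infer_positive(values)
    neg = values[0] if values[1] == pos else values[1]
    y = (raw == pos).to_numpy().astype(int)
    return y, pos, neg


# ---------------------------------------------------------------------------
# schema inference and bundled heart schema
# ---------------------------------------------------------------------------

def infer_schema(features: pd.DataFrame) -> list[ColumnSpec]:
    """Heuristic typing: <= 10 distinct integer values -> categorical."""
    specs = []
    for name in features.columns:
        vals = features[name].to_numpy(dtype=float)
        distinct = np.unique(vals)
        integral = np.allclose(distinct, np.round(distinct), atol=1e-9)
        if integral and 2 <= distinct.size <= CATEGORICAL_INFERENCE_MAX_LEVELS:
            specs.append(ColumnSpec(name, "categorical", tuple(np.round(distinct))))
        else:
            specs.append(ColumnSpec(name, "continuous"))
    return specs


def load_heart_schema() -> tuple[list[ColumnSpec], str, object]:
    """Bundled UCI heart-disease layout: (feature specs, target name, positive label)."""
    raw = json.loads(
        resources.files("asmote").joinpath("schemas/heart_uci.json").read_text()
    )
    specs = [
        ColumnSpec(c["name"], c["kind"], tuple(c["categories"]) if "categories" in c else None)
        for c in raw["columns"]
    ]
    return specs, raw["target"], raw["positive_label"]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv(
    path,
    target: str,
    schema: Sequence[ColumnSpec] | None = None,
    positive_label: object | None = None,
) -> Dataset:
    """Read a delimited table with header into a validated :class:`Dataset`.

    The target column is mapped to 0/1 (``positive_label`` forced to 1).  When
    ``schema`` is omitted, column kinds are inferred; otherwise each feature
    column must have a matching :class:`ColumnSpec` (extra entries, e.g. one
    for the target, are ignored).
    """
    df = pd.read_csv(path)
    if target not in df.columns:
        raise MissingTargetError(f"target column {target!r} not in header {list(df.columns)}")
    y, pos, neg = _encode_target(df[target], positive_label)
    features = df.drop(columns=[target])
    if features.shape[1] == 0:
        raise EmptyDatasetError("file has no feature columns besides the target")

    numeric = pd.DataFrame(index=features.index)
    for name in features.columns:
        col = pd.to_numeric(features[name], errors="coerce")
        if features[name].isna().any():
            raise MissingValueError(f"column {name!r} has missing values")
        if col.isna().any():
            bad = features[name][col.isna()].iloc[0]
            raise NonNumericValueError(f"non-numeric cell {bad!r} in column {name!r}")
        numeric[name] = col.astype(float)

    if schema is None:
        columns = infer_schema(numeric)
    else:
        by_name = {c.name: c for c in schema}
        missing = [n for n in numeric.columns if n not in by_name]
        if missing:
            raise SchemaMismatchError(f"schema lacks specs for columns {missing}")
        columns = [by_name[n] for n in numeric.columns]

    return Dataset(
        X=numeric.to_numpy(dtype=float),
        y=y,
        columns=columns,
        positive_label=pos,
        negative_label=neg,
        target_name=target,
    )


def write_csv(d: Dataset, path) -> None:
    """Write a dataset back to CSV so that re-reading reproduces it exactly.

    Categorical codes are written as integers when they are integral;
    the target column restores the original label values.
    """
    d.validate()
    frame = pd.DataFrame(d.X, columns=d.column_names)
    for j, col in enumerate(d.columns):
        if col.is_categorical and np.allclose(d.X[:, j], np.round(d.X[:, j])):
            frame[col.name] = frame[col.name].astype(int)
    labels = np.where(d.y == 1, d.positive_label, d.negative_label)
    frame[d.target_name] = labels
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# class split
# ---------------------------------------------------------------------------

def class_split(d: Dataset) -> ClassSplit:
    """Partition rows into minority (z) and majority (r) classes, z <= r.

    A tie in class frequency designates label 1 (disease present) as the
    minority, matching the convention that the positive class is the one
    oversampling protects.
    """
    n1 = int((d.y == 1).sum())
    n0 = d.n_samples - n1
    if n1 == 0 or n0 == 0:
        raise SingleClassError("both classes must be present to split")
    minority = 1 if n1 <= n0 else 0
    idx_m = np.flatnonzero(d.y == minority)
    idx_a = np.flatnonzero(d.y != minority)
    return ClassSplit(
        S_m=d.X[idx_m],
        S_a=d.X[idx_a],
        minority_label=minority,
        columns=list(d.columns),
        idx_m=idx_m,
        idx_a=idx_a,
    )
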