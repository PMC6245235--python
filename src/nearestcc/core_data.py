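"""Cohort data model: schema-driven CSV ingestion, imputation, scaling, labeling.

A cohort is a flat table with one row per patient: a mix of continuous
measurements (labs, lung function, age) and binary flags (antibody
presence), an optional class column, and optional time-to-event columns
(months to the event, plus an event/censoring status flag).

The schema is declared in a small YAML file so that dataset-specific
encodings (e.g. clinical registries that code binary variables as "1"/"2")
stay out of the code: each binary feature may carry a recode map from raw
codes to 0/1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
BINARY = "binary"

EVENT_OCCURRED = 1
EVENT_CENSORED = 0

#: default time-to-event threshold, months ("within the first 5 years")
DEFAULT_THRESHOLD_MONTHS = 60.0


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Schema:
    """Column layout of a cohort CSV.

    Parameters
    ----------
    feature_names
        Ordered feature column names.
    feature_kinds
        Mapping from feature name to ``"continuous"`` or ``"binary"``.
    class_column, time_column, event_column
        Optional names of the class label, months-to-event, and event-status
        columns. The event column holds 1 for an observed event and 0 for
        censoring (a recode map may translate other codes).
    positive_class
        The class label treated as "event before threshold"; used as the
        positive label in confusion metrics. Default ``"1"``.
    recodes
        Per-column mapping from raw codes (as strings) to stored values.
        Typically used for binary features coded "1"/"2".
    """

    feature_names: tuple[str, ...]
    feature_kinds: Mapping[str, str]
    class_column: str | None = None
    time_column: str | None = None
    event_column: str | None = None
    positive_class: str = "1"
    recodes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.feature_names
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        special = {self.class_column, self.time_column, self.event_column} - {None}
        overlap = special & set(names)
        if overlap:
            raise ValueError(f"feature names overlap special columns: {sorted(overlap)}")
        for name in names:
            kind = self.feature_kinds.get(name)
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"feature {name!r} has invalid kind {kind!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def kinds_array(self) -> np.ndarray:
        """Boolean mask, True where the feature is binary."""
        return np.array([self.feature_kinds[f] == BINARY for f in self.feature_names])

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": f, "kind": self.feature_kinds[f],
                 **({"recode": {str(k): float(v) for k, v in self.recodes[f].items()}}
                    if f in self.recodes else {})}
                for f in self.feature_names
            ],
            "class_column": self.class_column,
            "time_column": self.time_column,
            "event_column": self.event_column,
            "positive_class": self.positive_class,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Schema":
        feats = d["features"]
        names = tuple(f["name"] for f in feats)
        kinds = {f["name"]: f["kind"] for f in feats}
        recodes = {f["name"]: {str(k): float(v) for k, v in f["recode"].items()}
                   for f in feats if "recode" in f}
        return cls(
            feature_names=names,
            feature_kinds=kinds,
            class_column=d.get("class_column"),
            time_column=d.get("time_column"),
            event_column=d.get("event_column"),
            positive_class=str(d.get("positive_class", "1")),
            recodes=recodes,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """In-memory cohort: features, optional labels, optional survival columns.

    ``X`` is an (n, d) float array aligned with ``schema.feature_names``;
    binary features are stored as 0/1 (NaN marks a missing value before
    imputation). ``y`` is an object array of string labels (``None`` for
    unlabeled rows). ``time`` is months, ``event`` is 1/0
    (occurred/censored).
    """

    schema: Schema
    X: np.ndarray
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    row_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.schema.n_features:
            raise ValueError("X shape does not match schema")
        n = self.X.shape[0]
        if self.row_ids is None:
            self.row_ids = np.arange(n)
        for name in ("y", "time", "event", "row_ids"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")
        if self.time is not None:
            t = np.asarray(self.time, dtype=float)
            if np.any(t[~np.isnan(t)] < 0):
                raise ValueError("negative time-to-event values")
            self.time = t

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "CohortTable":
        """Row subset (copy), keeping all parallel columns aligned."""
        idx = np.asarray(idx)
        return CohortTable(
            schema=self.schema,
            X=self.X[idx].copy(),
            y=None if self.y is None else self.y[idx].copy(),
            time=None if self.time is None else self.time[idx].copy(),
            event=None if self.event is None else self.event[idx].copy(),
            row_ids=self.row_ids[idx].copy(),
        )

    def replace(self, **kw) -> "CohortTable":
        return dataclasses.replace(self, **kw)


def _recode_column(raw: pd.Series, recode: Mapping[str, float]) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return np.nan
        key = str(v)
        # integers read by pandas render as "1.0"; accept both spellings
        if key.endswith(".0"):
            key_alt = key[:-2]
        else:
            key_alt = key
        if key in recode:
            return recode[key]
        if key_alt in recode:
            return recode[key_alt]
        raise ValueError(f"value {v!r} not covered by recode map")
    return raw.map(one)


def read_cohort(path: str | Path, schema: Schema) -> CohortTable:
    """Read a header-row CSV into a :class:`CohortTable`.

    Raises a :class:`ValueError` naming the column when a schema column is
    absent, or naming the row and column when a continuous cell is not
    numeric. Rows missing the class label are retained with an absent label.
    """
    df = pd.read_csv(path)
    needed = list(schema.feature_names) + [
        c for c in (schema.class_column, schema.time_column, schema.event_column) if c
    ]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")

    cols = []
    for f in schema.feature_names:
        raw = df[f]
        if f in schema.recodes:
            raw = _recode_column(raw, schema.recodes[f])
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[f].iloc[row]!r} in column {f!r}, row {row}"
            )
        if schema.feature_kinds[f] == BINARY:
            ok = vals.isna() | vals.isin([0, 1])
            if not ok.all():
                row = int(np.flatnonzero(~ok.to_numpy())[0])
                raise ValueError(
                    f"binary column {f!r} has value {vals.iloc[row]!r} outside "
                    f"{{0,1}} at row {row}; declare a recode map in the schema"
                )
        cols.append(vals.to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    y = None
    if schema.class_column:
        raw = df[schema.class_column]
        y = np.array(
            [None if pd.isna(v) else _label_str(v) for v in raw], dtype=object
        )
    time = None
    if schema.time_column:
        time = pd.to_numeric(df[schema.time_column], errors="raise").to_numpy(float)
    event = None
    if schema.event_column:
        raw = df[schema.event_column]
        if schema.event_column in schema.recodes:
            raw = _recode_column(raw, schema.recodes[schema.event_column])
        event = pd.to_numeric(raw, errors="raise").to_numpy()
        if not np.all(np.isin(event[~pd.isna(event)], [0, 1])):
            raise ValueError("event column must be 0 (censored) / 1 (occurred)")
        event = event.astype(float)
    return CohortTable(schema=schema, X=X, y=y, time=time, event=event)


def _label_str(v) -> str:
    """Normalize a class label cell to a string ('1.0' -> '1')."""
    s = str(v)
    if s.endswith(".0"):
        s = s[:-2]
    return s


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV; exact float round-trip via repr."""
    data = {f: table.X[:, j] for j, f in enumerate(table.schema.feature_names)}
    s = table.schema
    if s.class_column and table.y is not None:
        data[s.class_column] = table.y
    if s.time_column and table.time is not None:
        data[s.time_column] = table.time
    if s.event_column and table.event is not None:
        data[s.event_column] = table.event
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Imputer:
    """Per-feature fill values learned from one table (train side only)."""

    fill: np.ndarray  # (d,) fill value per feature

    def apply(self, table: CohortTable) -> CohortTable:
        X = table.X.copy()
        for j in range(X.shape[1]):
            m = np.isnan(X[:, j])
            if m.any():
                X[m, j] = self.fill[j]
        return table.replace(X=X)


def fit_imputer(table: CohortTable) -> Imputer:
    """Column median for continuous gaps, column mode for binary (ties -> 0).

    A feature with no observed value at all is a hard error.
    """
    is_bin = table.schema.kinds_array()
    fill = np.empty(table.X.shape[1])
    for j in range(table.X.shape[1]):
        col = table.X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(
                f"feature {table.schema.feature_names[j]!r} is entirely missing"
            )
        if is_bin[j]:
            ones = int((obs == 1).sum())
            zeros = int(obs.size - ones)
            fill[j] = 1.0 if ones > zeros else 0.0
        else:
            fill[j] = float(np.median(obs))
    return Imputer(fill=fill)


def impute(table: CohortTable, imputer: Imputer | None = None) -> CohortTable:
    """Fill missing feature values; the input table is left untouched.

    When ``imputer`` is given its (training-set) statistics are used,
    otherwise fill values are computed from ``table`` itself.
    """
    if imputer is None:
        imputer = fit_imputer(table)
    return imputer.apply(table)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaler:
    """Z-scoring for continuous features; binary features pass through.

    Spread is the sample standard deviation (ddof=1); constant features get
    spread 1 so they map to exactly 0.
    """

    center: np.ndarray
    spread: np.ndarray
    is_binary: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.center.shape[0]:
            raise ValueError("dimension mismatch between scaler and data")
        return (X - self.center) / self.spread

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "is_binary": self.is_binary.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scaler":
        return cls(
            center=np.asarray(d["center"], float),
            spread=np.asarray(d["spread"], float),
            is_binary=np.asarray(d["is_binary"], bool),
        )


def fit_scaler(table: CohortTable) -> Scaler:
    """Fit on training rows only; test data must reuse this scaler."""
    if np.isnan(table.X).any():
        raise ValueError("impute before fitting the scaler")
    is_bin = table.schema.kinds_array()
    center = np.zeros(table.X.shape[1])
    spread = np.ones(table.X.shape[1])
    for j in range(table.X.shape[1]):
        if is_bin[j]:
            continue
        col = table.X[:, j]
        center[j] = float(np.mean(col))
        sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
        spread[j] = sd if sd > 0 else 1.0
    return Scaler(center=center, spread=spread, is_binary=is_bin)


def apply_scaler(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    return scaler.apply(X)


# ---------------------------------------------------------------------------
# Time-to-event labeling
# ---------------------------------------------------------------------------

def label_time_to_event(
    table: CohortTable, threshold_months: float = DEFAULT_THRESHOLD_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class labels from survival columns, with an inclusion mask.

    Class "1": the event occurred within ``threshold_months`` (inclusive).
    Class "2": the patient was followed past the threshold without the event
    by then (an event or censoring after the threshold).
    Excluded (mask False): censored before the threshold — their class is
    unknowable.

    Returns ``(labels, mask)``; ``labels`` is an object array with ``None``
    at excluded rows.
    """
    if table.time is None or table.event is None:
        raise ValueError("time and event columns required for labeling")
    t = np.asarray(table.time, float)
    if np.any(t < 0):
        raise ValueError("negative time-to-event values")
    e = np.asarray(table.event, float)
    labels = np.full(table.n_rows, None, dtype=object)
    event_before = (e == EVENT_OCCURRED) & (t <= threshold_months)
    followed_past = t >= threshold_months
    labels[event_before] = "1"
    labels[~event_before & followed_past] = "2"
    mask = labels != None  # noqa: E711 — object array comparison
    return labels, mask


def apply_event_labels(
    table: CohortTable, threshold_months: float = DEFAULT_THRESHOLD_MONTHS
) -> CohortTable:
    """Convenience: label by threshold and drop the excluded rows."""
    labels, mask = label_time_to_event(table, threshold_months)
    out = table.subset(np.flatnonzero(mask))
    out.y = labels[mask]
    return out
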