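"""Cohort and completed-data containers.

A :class:`Cohort` is a rectangular table of *n* subjects: a predictor matrix
with an explicit observed/missing mask, a per-column type specification
(continuous, binary, or categorical with a fixed level set), and a binary
outcome.  The outcome carries its own mask, which exists purely so that
cross-validation can hide validation-fold outcomes from the imputation model;
calibration data are expected to have the outcome observed everywhere.

Internally predictors are stored as a float matrix: continuous columns hold
their values, binary columns hold 0/1 codes, categorical columns hold level
codes ``0..L-1`` (reference-cell order fixed by the column spec).  ``NaN``
marks a missing cell.  This keeps the imputation and model-fitting hot paths
in plain numpy; :meth:`Cohort.to_frame` decodes back to labelled pandas data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTINUOUS",
    "BINARY",
    "CATEGORICAL",
    "ColumnSpec",
    "infer_column_spec",
    "Cohort",
    "CompletedData",
]

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSpec:
    """Kind of a predictor column plus, for discrete kinds, its fixed level
    set.  The level set is explicit and independent of which levels happen to
    be observed, so design matrices align across imputations and folds."""

    kind: str
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, BINARY, CATEGORICAL):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == BINARY and len(self.levels) != 2:
            raise ValueError("binary columns need exactly two levels")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise ValueError("categorical columns need at least two levels")
        if self.kind == CONTINUOUS and self.levels:
            raise ValueError("continuous columns carry no level set")


def infer_column_spec(series: pd.Series) -> ColumnSpec:
    """Infer a column kind from observed values.

    Numeric columns are continuous unless all observed values lie in
    ``{0, 1}`` (binary); non-numeric columns with two distinct labels are
    binary, otherwise categorical with the sorted label set.
    """
    obs = series.dropna()
    if len(obs) == 0:
        raise ValueError("cannot infer a column kind without observed values")
    numeric = pd.to_numeric(obs, errors="coerce")
    if not numeric.isna().any():
        vals = set(np.unique(numeric.to_numpy(dtype=float)))
        if vals <= {0.0, 1.0}:
            return ColumnSpec(BINARY, (0, 1))
        return ColumnSpec(CONTINUOUS)
    levels = tuple(sorted(obs.astype(str).unique()))
    if len(levels) == 1:
        raise ValueError("column has a single observed level; kind is ambiguous")
    if len(levels) == 2:
        return ColumnSpec(BINARY, levels)
    return ColumnSpec(CATEGORICAL, levels)


def _encode_column(series: pd.Series, spec: ColumnSpec, name: str) -> np.ndarray:
    n = len(series)
    if spec.kind == CONTINUOUS:
        vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        bad = series.notna().to_numpy() & np.isnan(vals)
        if bad.any():
            raise ValueError(f"non-numeric value in continuous column {name!r}")
        return vals

    out = np.full(n, np.nan)
    if pd.api.types.is_numeric_dtype(series):
        vals = series.to_numpy(dtype=float)
        for code, lev in enumerate(spec.levels):
            try:
                out[vals == float(lev)] = code
            except (TypeError, ValueError):
                continue
        bad = series.notna().to_numpy() & np.isnan(out)
    else:
        lookup = {}
        for code, lev in enumerate(spec.levels):
            lookup[lev] = float(code)
            lookup[str(lev)] = float(code)
        arr = series.to_numpy(dtype=object)
        for pos in range(n):
            v = arr[pos]
            if pd.isna(v):
                continue
            if v in lookup:
                out[pos] = lookup[v]
            elif str(v) in lookup:
                out[pos] = lookup[str(v)]
        bad = series.notna().to_numpy() & np.isnan(out)
    if bad.any():
        raise ValueError(
            f"value outside the declared level set {spec.levels!r} "
            f"in column {name!r}"
        )
    return out


def _decode_column(codes: np.ndarray, spec: ColumnSpec):
    if spec.kind == CONTINUOUS:
        return codes.copy()
    if all(isinstance(lev, (int, float, np.integer, np.floating)) for lev in spec.levels):
        table = np.asarray(spec.levels, dtype=float)
        out = np.full(codes.shape, np.nan)
        ok = ~np.isnan(codes)
        out[ok] = table[codes[ok].astype(int)]
        return out
    out = np.full(codes.shape, np.nan, dtype=object)
    ok = ~np.isnan(codes)
    out[ok] = np.asarray(spec.levels, dtype=object)[codes[ok].astype(int)]
    return out


class Cohort:
    """Predictors with a missingness mask plus a binary outcome.

    Parameters
    ----------
    predictors : DataFrame-like
        n x p table; ``NaN`` (or missing tokens already parsed to NaN) marks
        missing predictor cells.  May include the outcome column when
        ``outcome`` is passed as its name.
    outcome : str or array-like
        Name of the outcome column inside ``predictors`` or a length-n vector
        of 0/1 values (``NaN`` only for deliberately masked rows).
    column_spec : mapping, optional
        Per-column :class:`ColumnSpec`; inferred where absent.
    """

    def __init__(self, predictors, outcome, column_spec=None, outcome_name=None):
        df = pd.DataFrame(predictors)
        if isinstance(outcome, str):
            if outcome not in df.columns:
                raise KeyError(f"outcome column {outcome!r} not found")
            y_raw = df[outcome]
            df = df.drop(columns=[outcome])
            outcome_name = outcome_name or outcome
        else:
            y_raw = pd.Series(np.asarray(outcome), index=df.index)
            outcome_name = outcome_name or "outcome"
        if df.shape[1] == 0:
            raise ValueError("cohort needs at least one predictor column")
        if df.index.has_duplicates:
            raise ValueError("duplicate row identifiers in cohort")

        columns = [str(c) for c in df.columns]
        spec_map = dict(column_spec or {})
        specs = []
        X = np.empty(df.shape, dtype=float)
        for j, c in enumerate(df.columns):
            spec = spec_map.get(c, spec_map.get(str(c)))
            if spec is None:
                spec = infer_column_spec(df[c])
            specs.append(spec)
            X[:, j] = _encode_column(df[c], spec, str(c))

        observed = ~np.isnan(X)
        for j, c in enumerate(columns):
            if not observed[:, j].any():
                raise ValueError(f"column {c!r} has no observed values")

        y = pd.to_numeric(y_raw, errors="coerce").to_numpy(dtype=float)
        if (y_raw.notna().to_numpy() & np.isnan(y)).any():
            raise ValueError("outcome contains non-numeric values")
        yobs = ~np.isnan(y)
        if yobs.any() and not set(np.unique(y[yobs])) <= {0.0, 1.0}:
            raise ValueError("outcome values must be exactly 0 or 1 where observed")

        self.columns: list[str] = columns
        self.specs: tuple[ColumnSpec, ...] = tuple(specs)
        self.X: np.ndarray = X
        self.observed: np.ndarray = observed
        self.y: np.ndarray = y
        self.row_id: pd.Index = df.index.copy()
        self.outcome_name: str = str(outcome_name)

    # -- lightweight cloning (skips re-validation in the CV hot loop) -------
    @classmethod
    def _from_internal(cls, columns, specs, X, observed, y, row_id, outcome_name):
        obj = object.__new__(cls)
        obj.columns = columns
        obj.specs = specs
        obj.X = X
        obj.observed = observed
        obj.y = y
        obj.row_id = row_id
        obj.outcome_name = outcome_name
        return obj

    # -- basic shape --------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def y_observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def fully_observed(self) -> np.ndarray:
        """Per-row flag: no missing predictor cell (record status used to
        partition evaluation summaries, never to restrict model fitting)."""
        return self.observed.all(axis=1)

    @property
    def n_missing_outcomes(self) -> int:
        return int(np.isnan(self.y).sum())

    # -- outcome masking for cross-validation -------------------------------
    def mask_outcomes(self, rows) -> "Cohort":
        """Return a copy with the outcome marked missing (value discarded)
        for ``rows`` (boolean mask or integer positions).  Predictors are
        untouched and shared."""
        rows = np.asarray(rows)
        if rows.dtype != bool:
            idx = np.zeros(self.n, dtype=bool)
            idx[rows] = True
        else:
            if rows.shape != (self.n,):
                raise ValueError("boolean row mask has wrong length")
            idx = rows
        y = self.y.copy()
        y[idx] = np.nan
        return Cohort._from_internal(
            self.columns, self.specs, self.X, self.observed, y,
            self.row_id, self.outcome_name,
        )

    def restore_outcomes(self, values) -> "Cohort":
        """Fill masked outcome cells from ``values`` (a full-length vector),
        inverting :meth:`mask_outcomes`."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError("outcome vector has wrong length")
        y = np.where(np.isnan(self.y), values, self.y)
        obs = ~np.isnan(y)
        if obs.any() and not set(np.unique(y[obs])) <= {0.0, 1.0}:
            raise ValueError("restored outcome values must be 0 or 1")
        return Cohort._from_internal(
            self.columns, self.specs, self.X, self.observed, y,
            self.row_id, self.outcome_name,
        )

    # -- predictor masking (simulation mechanisms) ---------------------------
    def mask_predictor_cells(self, column: str, rows) -> "Cohort":
        """Return a copy with ``column`` set missing in ``rows``."""
        j = self.columns.index(column)
        rows = np.asarray(rows)
        if rows.dtype != bool:
            idx = np.zeros(self.n, dtype=bool)
            idx[rows] = True
        else:
            idx = rows
        X = self.X.copy()
        observed = self.observed.copy()
        X[idx, j] = np.nan
        observed[idx, j] = False
        if not observed[:, j].any():
            raise ValueError(f"masking would leave column {column!r} without observed values")
        return Cohort._from_internal(
            self.columns, self.specs, X, observed, self.y,
            self.row_id, self.outcome_name,
        )

    # -- conversion ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            c: _decode_column(self.X[:, j], self.specs[j])
            for j, c in enumerate(self.columns)
        }
        data[self.outcome_name] = self.y.copy()
        return pd.DataFrame(data, index=self.row_id)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.columns == other.columns
            and self.specs == other.specs
            and np.array_equal(self.X, other.X, equal_nan=True)
            and np.array_equal(self.y, other.y, equal_nan=True)
            and self.row_id.equals(other.row_id)
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        kinds = ",".join(s.kind[0] for s in self.specs)
        return (
            f"Cohort(n={self.n}, p={self.n_predictors} [{kinds}], "
            f"missing_cells={int((~self.observed).sum())}, "
            f"masked_outcomes={self.n_missing_outcomes})"
        )


@dataclass
class CompletedData:
    """One imputation draw: the cohort's predictor matrix with every missing
    cell filled in.  Observed cells are bit-identical to the source cohort.

    ``outcome_imputed`` holds the full outcome vector with masked entries
    replaced by their (ephemeral) imputed values; it exists only because the
    chained-equations cycle needs a complete outcome column and is discarded
    by the cross-validation driver.
    """

    cohort: Cohort
    X: np.ndarray
    k: int = 0
    outcome_imputed: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != self.cohort.X.shape:
            raise ValueError("completed matrix shape mismatch")
        if np.isnan(self.X).any():
            raise ValueError("completed data may not contain missing cells")
        obs = self.cohort.observed
        if not np.array_equal(self.X[obs], self.cohort.X[obs]):
            raise ValueError("completed data altered observed cells")

    def to_frame(self) -> pd.DataFrame:
        data = {
            c: _decode_column(self.X[:, j], self.cohort.specs[j])
            for j, c in enumerate(self.cohort.columns)
        }
        return pd.DataFrame(data, index=self.cohort.row_id)
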