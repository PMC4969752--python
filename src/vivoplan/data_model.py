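"""Typed ingestion, validation and output of study tables.

Two tables drive a matched preclinical study: a wide baseline covariate
table (one row per experimental unit — animal or tumor — with numeric and
categorical covariates measured before any intervention, plus an optional
batch label), and a long-format longitudinal response table (one row per
unit per time point, e.g. weekly serum PSA in a xenograft study).

Tables are held as pandas DataFrames behind thin validated wrappers.
Missing covariate values are preserved on read and never imputed; modules
that consume a covariate with missing values raise instead of guessing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTable",
    "LongitudinalTable",
    "DataError",
    "read_covariates",
    "read_longitudinal",
    "write_covariates",
    "write_longitudinal",
    "write_allocation",
    "read_allocation",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CovariateTable:
    """Baseline covariates for the units entering the matching.

    Parameters
    ----------
    data
        DataFrame indexed by unit id with one column per covariate.
    kinds
        Maps each covariate column to ``"numeric"`` or ``"categorical"``.
    batch
        Optional categorical batch label per unit (aligned to ``data``).
    weights
        Optional per-covariate nonnegative importance weight; covariates
        not listed default to 1.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    batch: pd.Series | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.data.index
        if ids.has_duplicates:
            dups = sorted(set(ids[ids.duplicated()].astype(str)))
            raise DataError(f"duplicate unit ids: {dups}")
        if any(str(u) == "" or pd.isna(u) for u in ids):
            raise DataError("unit ids must be nonempty")
        for col in self.data.columns:
            if col not in self.kinds:
                raise DataError(f"column {col!r} has no declared kind (numeric/categorical)")
        for col, kind in self.kinds.items():
            if kind not in (NUMERIC, CATEGORICAL):
                raise DataError(f"column {col!r}: unknown kind {kind!r}")
            if col not in self.data.columns:
                raise DataError(f"declared column {col!r} missing from data")
        for col in self.numeric_columns:
            vals = self.data[col]
            ok = vals.isna() | vals.map(lambda v: isinstance(v, (int, float, np.integer, np.floating)))
            if not ok.all():
                bad = self.data.index[~ok][0]
                raise DataError(f"column {col!r} declared numeric but unit {bad!r} has a non-numeric value")
        for cov, w in self.weights.items():
            if cov not in self.kinds:
                raise DataError(f"weight given for unknown covariate {cov!r}")
            if w < 0:
                raise DataError(f"weight for {cov!r} must be nonnegative, got {w}")
        if self.batch is not None and not self.batch.index.equals(self.data.index):
            raise DataError("batch series must be indexed like the covariate data")

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.data.index]

    @property
    def n_units(self) -> int:
        return len(self.data)

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == NUMERIC]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == CATEGORICAL]

    def weight(self, covariate: str) -> float:
        return float(self.weights.get(covariate, 1.0))

    def batch_blocks(self) -> dict[str, list[str]]:
        """Unit ids grouped by batch label ({'': all} when batch-free)."""
        if self.batch is None:
            return {"": self.unit_ids}
        out: dict[str, list[str]] = {}
        for uid, b in self.batch.items():
            out.setdefault(str(b), []).append(str(uid))
        return out

    def subset(self, unit_ids: Sequence[str]) -> "CovariateTable":
        sub = self.data.loc[list(unit_ids)]
        batch = self.batch.loc[list(unit_ids)] if self.batch is not None else None
        return CovariateTable(sub, dict(self.kinds), batch, dict(self.weights))


@dataclass
class LongitudinalTable:
    """Long-format longitudinal responses.

    Columns: ``unit_id``, ``time`` (nonnegative ordinal index, 0 at
    baseline), ``response`` (numeric), ``arm`` (intervention-group label).
    """

    data: pd.DataFrame

    REQUIRED = ("unit_id", "time", "response", "arm")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"longitudinal table missing columns: {missing}")
        if len(df) == 0:
            raise DataError("no observations")
        if df.duplicated(subset=["unit_id", "time"]).any():
            dup = df[df.duplicated(subset=["unit_id", "time"])].iloc[0]
            raise DataError(f"duplicate (unit_id, time) pair: ({dup['unit_id']!r}, {dup['time']!r})")
        arms_per_unit = df.groupby("unit_id")["arm"].nunique()
        multi = arms_per_unit[arms_per_unit > 1]
        if len(multi):
            raise DataError(f"units appear under more than one arm: {sorted(multi.index.astype(str))}")
        if (pd.to_numeric(df["time"]) < 0).any():
            raise DataError("time indices must be nonnegative")
        if not (pd.to_numeric(df["time"]) == 0).any():
            raise DataError("no unit has a baseline (time = 0) observation")
        self.data = df.sort_values(["unit_id", "time"], kind="mergesort").reset_index(drop=True)

    @property
    def unit_ids(self) -> list[str]:
        return sorted(self.data["unit_id"].astype(str).unique())

    @property
    def arms(self) -> list[str]:
        return sorted(self.data["arm"].astype(str).unique())

    def arm_of(self) -> dict[str, str]:
        return {str(u): str(a) for u, a in self.data.groupby("unit_id")["arm"].first().items()}

    def trajectory(self, unit_id: str) -> pd.DataFrame:
        """Time-sorted (time, response) rows for one unit."""
        sub = self.data[self.data["unit_id"].astype(str) == str(unit_id)]
        if len(sub) == 0:
            raise DataError(f"unknown unit {unit_id!r}")
        return sub[["time", "response"]].reset_index(drop=True)


def read_covariates(
    path: str | Path,
    schema: Mapping[str, str],
    id_column: str = "unit_id",
    batch_column: str | None = None,
    weights: Mapping[str, float] | None = None,
) -> CovariateTable:
    """Read and validate a baseline covariate CSV.

    ``schema`` declares the kind (``"numeric"`` / ``"categorical"``) of every
    covariate column. A column named ``batch`` (or ``batch_column``) is
    treated as the batch label and needs no schema entry. Missing values
    stay missing — no imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise DataError(f"{path}: no id column {id_column!r}")
    if batch_column is None and "batch" in df.columns:
        batch_column = "batch"
    dup_mask = df[id_column].duplicated()
    if dup_mask.any():
        raise DataError(f"{path}: duplicate unit ids: {sorted(df[id_column][dup_mask].unique())}")
    df = df.set_index(id_column)
    batch = None
    if batch_column is not None:
        if batch_column not in df.columns:
            raise DataError(f"{path}: no batch column {batch_column!r}")
        batch = df[batch_column].astype(str)
        df = df.drop(columns=[batch_column])
    undeclared = [c for c in df.columns if c not in schema]
    if undeclared:
        raise DataError(f"{path}: columns with undeclared kind: {undeclared}")
    kinds = {c: schema[c] for c in df.columns}
    for col, kind in kinds.items():
        if kind == NUMERIC:
            df[col] = pd.to_numeric(df[col], errors="raise")
        else:
            df[col] = df[col].astype("string").astype(object)
    return CovariateTable(df, kinds, batch, dict(weights or {}))


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    df = table.data.copy()
    if table.batch is not None:
        df["batch"] = table.batch
    df.index.name = "unit_id"
    df.to_csv(path)


def read_longitudinal(path: str | Path) -> LongitudinalTable:
    """Read and validate a long-format response CSV (unit_id,time,response,arm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        df = pd.read_csv(path, dtype={"unit_id": str, "arm": str})
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: no observations") from None
    if len(df) == 0:
        raise DataError(f"{path}: no observations")
    df["time"] = pd.to_numeric(df["time"])
    df["response"] = pd.to_numeric(df["response"])
    return LongitudinalTable(df)


def write_longitudinal(table: LongitudinalTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_allocation(plan, path: str | Path, blinded: bool = False, key_path: str | Path | None = None) -> None:
    """Write an allocation plan as CSV.

    Unblinded output has columns ``unit_id,submatch,arm``. Blinded output
    replaces ``arm`` with the coded label (``code``) and writes a separate
    code→arm key file (default ``<path>.key.csv``) so experimenters never
    see the arm identities; the key is meant for the unblinding party only.
    """
    missing = [u for u, rec in plan.assignments.items() if rec is None]
    if missing:
        raise DataError(f"partial plan: units without assignment: {sorted(missing)}")
    path = Path(path)
    rows = []
    for uid in plan.unit_ids:
        sub, arm, code = plan.assignments[uid]
        rows.append((uid, sub, code if blinded else arm))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "submatch", "code" if blinded else "arm"])
        w.writerows(rows)
    if blinded:
        key_path = Path(key_path) if key_path is not None else path.with_suffix(".key.csv")
        with open(key_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "arm"])
            for code, arm in sorted(plan.code_to_arm.items()):
                w.writerow([code, arm])


def read_allocation(path: str | Path, key_path: str | Path | None = None) -> pd.DataFrame:
    """Read an allocation CSV; if a key file is given, decode blinded labels."""
    df = pd.read_csv(path, dtype=str)
    if "unit_id" not in df.columns or "submatch" not in df.columns:
        raise DataError(f"{path}: expected unit_id and submatch columns")
    df["submatch"] = df["submatch"].astype(int)
    if key_path is not None:
        key = pd.read_csv(key_path, dtype=str).set_index("code")["arm"]
        df["arm"] = df["code"].map(key)
        if df["arm"].isna().any():
            raise DataError("blinded code missing from key file")
    if "arm" not in df.columns:
        raise DataError(f"{path}: no arm column and no key file to decode codes")
    return df
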