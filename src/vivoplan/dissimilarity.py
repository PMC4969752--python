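"""Pairwise baseline dissimilarity matrices for mixed-type covariates.

The matching step consumes a symmetric N x N matrix D whose entry D[i, j]
quantifies how different units i and j are at baseline. Numeric covariates
enter through a chosen metric; categorical covariates enter either in
*relaxed* mode (each label mismatch adds a fixed penalty, so strong numeric
similarity can still place two units in the same submatch) or in *strict*
mode (a mismatch sets the distance to +inf, forbidding co-membership and
forcing every stratum to spread evenly over the arms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import CovariateTable, DataError

__all__ = [
    "DissimilarityMatrix",
    "compute_dissimilarity",
    "validate_dissimilarity",
    "read_matrix",
    "write_matrix",
    "METRICS",
]

METRICS = ("euclidean", "standardized-euclidean", "mahalanobis", "manhattan", "gower")


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative matrix of baseline distances; +inf entries allowed."""

    values: np.ndarray
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError(f"dissimilarity matrix must be square, got shape {self.values.shape}")
        if not self.unit_ids:
            self.unit_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.unit_ids) != self.values.shape[0]:
            raise DataError("unit_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, idx):
        return self.values[idx]


def _numeric_matrix(table: CovariateTable) -> tuple[np.ndarray, list[str]]:
    cols = table.numeric_columns
    X = table.data[cols].to_numpy(dtype=float) if cols else np.empty((table.n_units, 0))
    if np.isnan(X).any():
        bad_cols = [c for i, c in enumerate(cols) if np.isnan(X[:, i]).any()]
        raise DataError(
            f"missing values in numeric covariates {bad_cols}; "
            "drop the units or the covariates before matching (no imputation is performed)"
        )
    return X, cols


def compute_dissimilarity(
    table: CovariateTable,
    metric: str = "standardized-euclidean",
    categorical_mode: str = "relaxed",
    relaxed_penalty: float = 1.0,
) -> DissimilarityMatrix:
    """Compute the N x N baseline dissimilarity matrix.

    Parameters
    ----------
    table
        Validated baseline covariate table (missing values are an error).
    metric
        Distance on the numeric covariates: ``euclidean``, ``manhattan``,
        ``standardized-euclidean`` (z-score each column first; default,
        scale-free across heterogeneous units such as grams and ug/l),
        ``mahalanobis`` (decorrelating; needs a nonsingular covariance) or
        ``gower`` (range-normalized mean absolute difference).
    categorical_mode
        ``relaxed``: each mismatching categorical covariate adds
        ``relaxed_penalty`` times its weight to D[i, j]. ``strict``:
        any mismatch sets D[i, j] = +inf.
    relaxed_penalty
        Nonnegative penalty per categorical mismatch, on the scale of the
        numeric metric (default 1.0 — one z-score unit under the default
        standardized metric).

    Per-covariate weights from the table multiply each covariate's
    contribution before aggregation.
    """
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}; choose one of {METRICS}")
    if categorical_mode not in ("relaxed", "strict"):
        raise DataError(f"categorical_mode must be 'relaxed' or 'strict', got {categorical_mode!r}")
    if relaxed_penalty < 0:
        raise DataError(f"relaxed_penalty must be nonnegative, got {relaxed_penalty}")
    n = table.n_units
    if n < 2:
        raise DataError("need at least 2 units to match")

    X, num_cols = _numeric_matrix(table)
    w = np.array([table.weight(c) for c in num_cols])

    if X.shape[1] == 0:
        D = np.zeros((n, n))
    elif metric == "euclidean":
        D = squareform(pdist(X * np.sqrt(w), metric="euclidean"))
    elif metric == "manhattan":
        D = squareform(pdist(X * w, metric="cityblock"))
    elif metric == "standardized-euclidean":
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"zero-variance numeric covariates contribute 0: {[c for c, z in zip(num_cols, zero) if z]}")
            sd = np.where(zero, 1.0, sd)
        D = squareform(pdist((X / sd) * np.sqrt(w), metric="euclidean"))
    elif metric == "mahalanobis":
        if X.shape[1] == 1:
            cov = np.atleast_2d(np.var(X, axis=0, ddof=1))
        else:
            cov = np.cov(X, rowvar=False)
        try:
            VI = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            raise DataError(
                "numeric covariate covariance is singular; mahalanobis is undefined "
                "(consider the standardized-euclidean metric)"
            ) from None
        if not np.all(np.isfinite(VI)) or np.linalg.cond(cov) > 1e12:
            raise DataError(
                "numeric covariate covariance is (near-)singular; mahalanobis is undefined "
                "(consider the standardized-euclidean metric)"
            )
        D = squareform(pdist(X, metric="mahalanobis", VI=VI))
    else:  # gower
        rng = X.max(axis=0) - X.min(axis=0)
        zero = rng == 0
        if zero.any():
            warnings.warn(f"zero-range columns contribute 0 to Gower distance: {[c for c, z in zip(num_cols, zero) if z]}")
            rng = np.where(zero, 1.0, rng)
        wsum = w.sum() if w.sum() > 0 else 1.0
        parts = np.abs(X[:, None, :] - X[None, :, :]) / rng  # per-column in [0, 1]
        D = (parts * w).sum(axis=2) / wsum
        np.fill_diagonal(D, 0.0)

    for col in table.categorical_columns:
        labels = table.data[col].to_numpy(dtype=object)
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in labels):
            raise DataError(f"missing values in categorical covariate {col!r}")
        mismatch = labels[:, None] != labels[None, :]
        if categorical_mode == "strict":
            D = np.where(mismatch, np.inf, D)
        else:
            D = D + mismatch * (relaxed_penalty * table.weight(col))

    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D, table.unit_ids)


def validate_dissimilarity(D: DissimilarityMatrix, atol: float = 1e-10) -> list[str]:
    """Diagnostic report of symmetry / zero-diagonal / nonnegativity violations.

    Returns an empty list iff the matrix is a valid dissimilarity matrix.
    """
    V = D.values
    report: list[str] = []
    finite_both = np.isfinite(V) & np.isfinite(V.T)
    asym = (finite_both & (np.abs(V - V.T) > atol)) | (np.isfinite(V) != np.isfinite(V.T))
    for i, j in zip(*np.nonzero(np.triu(asym, 1))):
        report.append(f"asymmetry at ({D.unit_ids[i]}, {D.unit_ids[j]}): {V[i, j]} != {V[j, i]}")
    diag = np.diagonal(V)
    for i in np.nonzero(np.abs(diag) > atol)[0]:
        report.append(f"nonzero diagonal at {D.unit_ids[i]}: {diag[i]}")
    neg = np.isfinite(V) & (V < -atol)
    for i, j in zip(*np.nonzero(neg)):
        report.append(f"negative entry at ({D.unit_ids[i]}, {D.unit_ids[j]}): {V[i, j]}")
    return report


def write_matrix(D: DissimilarityMatrix, path) -> None:
    """Square CSV with a unit-id header row/column; +inf written as ``inf``."""
    import pandas as pd

    pd.DataFrame(D.values, index=D.unit_ids, columns=D.unit_ids).to_csv(path)


def read_matrix(path) -> DissimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])
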