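"""Data containers and delimited-table I/O for right-censored regression.

The observable sample consists of ``n`` i.i.d. triples ``(X_i, Z_i, delta_i)``
where ``X_i`` is a p-vector of covariates, ``Z_i = min(Y_i, C_i)`` is the
response observed on the analysis scale (for survival data typically a log
survival time), and ``delta_i = I[Y_i <= C_i]`` indicates whether the event
was observed (1) or censored (0).  Inference targets the slope vector of the
semiparametric linear (accelerated failure time) model

    Y_i = X_i' beta + eps_i,

whose i.i.d. errors have a completely unspecified distribution.  The model
carries no intercept: the error distribution absorbs location, so only the
slopes are identifiable.  Responses are assumed pre-transformed (or
transformed at read time via ``transform=``); no module in this package ever
log-transforms internally, and no intercept column is ever added.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensoredRegressionData",
    "SchemaError",
    "read_survival_table",
    "write_survival_table",
    "residuals",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class CensoredRegressionData:
    """A validated right-censored regression sample ``(X, Z, delta)``.

    Parameters
    ----------
    X : (n, p) array
        Covariate matrix.  A 1-d array is treated as a single covariate.
    Z : (n,) array
        Observed response ``min(Y, C)`` on the analysis scale.
    delta : (n,) array of {0, 1}
        Event indicator; 1 = event observed, 0 = right censored.  No other
        encoding is accepted (this guards against silently flipped
        indicators).

    Raises
    ------
    ValueError
        If lengths disagree, ``n < p + 2``, ``delta`` contains values outside
        {0, 1}, every observation is censored, values are non-finite, or the
        sample covariance of the covariates is rank deficient (the model
        requires a positive-definite covariate covariance).
    """

    X: np.ndarray
    Z: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("X must be a 1-d or 2-d array")
        Z = np.asarray(self.Z, dtype=float).ravel()
        d = np.asarray(self.delta).ravel()
        n, p = X.shape
        if Z.shape[0] != n or d.shape[0] != n:
            raise ValueError("X, Z and delta must share the same length n")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("delta must contain only 0 (censored) and 1 (event)")
        d = d.astype(np.int8)
        if not (np.isfinite(X).all() and np.isfinite(Z).all()):
            raise ValueError("non-finite values in X or Z")
        if n < p + 2:
            raise ValueError(f"need at least p + 2 = {p + 2} observations, got {n}")
        if int(d.sum()) == 0:
            raise ValueError("all observations are censored: no events to anchor the fit")
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
            raise ValueError("sample covariance of X is rank deficient")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "delta", d)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    @property
    def censoring_rate(self) -> float:
        return 1.0 - self.n_events / self.n


def _check_beta(beta, p: int) -> np.ndarray:
    b = np.asarray(beta, dtype=float).ravel()
    if b.shape[0] != p:
        raise ValueError(f"beta has length {b.shape[0]}, expected p = {p}")
    if not np.isfinite(b).all():
        raise ValueError("beta must be finite")
    return b


def residuals(data: CensoredRegressionData, beta) -> np.ndarray:
    """Model residuals ``e_i = Z_i - X_i' beta`` (length n, paired with delta).

    For censored subjects this is a censored version of the error, not the
    error itself; downstream modules carry ``delta`` alongside.
    """
    b = _check_beta(beta, data.p)
    return data.Z - data.X @ b


_TRANSFORMS = {
    "none": lambda y: y,
    "log": np.log,
    "log10": np.log10,
}


def read_survival_table(
    path,
    response_col: str,
    status_col: str,
    covariate_cols: Sequence[str],
    transform: str = "none",
    sep: str | None = None,
) -> CensoredRegressionData:
    """Read a delimited survival table into a :class:`CensoredRegressionData`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.  The delimiter is inferred from the
        extension (``.tsv`` -> tab, otherwise comma) unless ``sep`` is given.
    response_col, status_col : str
        Column names for the observed time/response and the {0, 1} event
        indicator.
    covariate_cols : sequence of str
        Covariate column names, in order.
    transform : {"none", "log", "log10"}
        Optional transform applied to the response at read time; requires a
        strictly positive response.

    Missing values in any used column are rejected (no imputation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = [response_col, status_col, *covariate_cols]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path.name}; found {list(df.columns)}")
    sub = df[cols]
    if sub.isna().any().any():
        bad = int(sub.isna().any(axis=1).sum())
        raise ValueError(f"{bad} row(s) contain missing values; remove them before reading")
    y = sub[response_col].to_numpy(dtype=float)
    if transform != "none" and np.any(y <= 0):
        raise ValueError(f"response must be strictly positive for transform={transform!r}")
    Z = _TRANSFORMS[transform](y)
    return CensoredRegressionData(
        X=sub[list(covariate_cols)].to_numpy(dtype=float),
        Z=Z,
        delta=sub[status_col].to_numpy(),
    )


def write_survival_table(
    data: CensoredRegressionData,
    path,
    response_col: str = "time",
    status_col: str = "status",
    covariate_cols: Sequence[str] | None = None,
    sep: str | None = None,
) -> None:
    """Write a sample back to CSV/TSV; round-trips exactly with the reader."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if covariate_cols is None:
        covariate_cols = [f"x{j + 1}" for j in range(data.p)]
    if len(covariate_cols) != data.p:
        raise ValueError("covariate_cols length must equal p")
    df = pd.DataFrame({response_col: data.Z, status_col: data.delta.astype(int)})
    for j, name in enumerate(covariate_cols):
        df[name] = data.X[:, j]
    df.to_csv(path, sep=sep, index=False)
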