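"""Buckley-James imputation, estimating function, and point estimator.

A censored response carries partial information: given ``Z_i`` and the
residual distribution ``F``, the conditional expectation of the unobserved
``Y_i`` is

    Y_i* = delta_i Z_i
           + (1 - delta_i) [ X_i' beta + E_F( e | e > Z_i - X_i' beta ) ],

where the conditional tail mean is taken under the product-limit estimate
``F_hat(beta)`` of the residual distribution (refit at every ``beta``).  The
estimating function centers the covariates at the sample mean,

    W_i(beta) = (X_i - Xbar) (Y_i* - X_i' beta),

and the Buckley-James normal equation sets its column sums to zero.  With no
censoring the whole machinery collapses exactly to ordinary least squares of
``Z`` on the centered covariates.

Degenerate tails: a censored residual at or beyond the largest event
residual leaves no mass strictly above it even after tail completion; such a
subject is imputed with the largest observed residual (bounded and keeps the
subject in the fit).

The point-estimate iteration beta -> least-squares fit of the imputed
responses is not a contraction in general and can settle into a cycle; a
detected cycle is resolved by averaging the iterates along the cycle and
flagging the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CensoredRegressionData, _check_beta, residuals
from .km import KMCurve, km_fit, tail_means

__all__ = [
    "EstimatingFunctionMatrix",
    "BJFit",
    "impute_responses",
    "estimating_function",
    "bj_point_estimate",
]


@dataclass(frozen=True)
class EstimatingFunctionMatrix:
    """Rows ``W_i(beta)`` of the Buckley-James estimating function.

    ``W.sum(axis=0)`` is the normal-equation discrepancy at ``beta_at``.
    """

    W: np.ndarray
    beta_at: np.ndarray
    mean_vec: np.ndarray


@dataclass(frozen=True)
class BJFit:
    """Buckley-James point estimate with convergence diagnostics."""

    beta: np.ndarray
    iterations: int
    converged: bool
    cycle: bool


def _residual_curve(data: CensoredRegressionData, beta) -> tuple[np.ndarray, KMCurve]:
    e = residuals(data, beta)
    return e, km_fit(e, data.delta, largest_as_event=True)


def imputed_residuals(
    data: CensoredRegressionData, beta, curve: KMCurve | None = None, e=None
) -> np.ndarray:
    """Per-subject residual contribution ``delta_i e_i + (1-delta_i) E[e|e>e_i]``."""
    if e is None or curve is None:
        e, curve = _residual_curve(data, beta)
    out = e.astype(float, copy=True)
    cens = data.delta == 0
    if cens.any():
        out[cens] = tail_means(curve, e[cens], fallback="max_support")
    return out


def impute_responses(data: CensoredRegressionData, beta) -> np.ndarray:
    """Buckley-James imputed responses ``Y_i*`` at the candidate slope."""
    b = _check_beta(beta, data.p)
    xb = data.X @ b
    # events keep Z exactly (xb + e_i would only round-trip in floating point)
    return np.where(data.delta == 1, data.Z, xb + imputed_residuals(data, b))


def estimating_function(data: CensoredRegressionData, beta) -> EstimatingFunctionMatrix:
    """Estimating-function rows ``(X_i - Xbar)(Y_i* - X_i' beta)``."""
    b = _check_beta(beta, data.p)
    xbar = data.X.mean(axis=0)
    rstar = imputed_residuals(data, b)
    W = (data.X - xbar) * rstar[:, None]
    return EstimatingFunctionMatrix(W=W, beta_at=b, mean_vec=xbar)


def bj_point_estimate(
    data: CensoredRegressionData,
    beta0=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    cycle_window: int = 10,
) -> BJFit:
    """Iterative Buckley-James slope estimate.

    Iterates the least-squares update on imputed responses,

        beta_{k+1} = (Xc' Xc)^{-1} Xc' Y*(beta_k),   Xc = X - Xbar,

    from ``beta0`` (default: OLS of ``Z`` on the centered covariates) until
    successive iterates move less than ``tol``.  If an iterate returns within
    ``tol`` of a non-adjacent previous iterate inside a sliding window, the
    map is cycling; the average over the detected cycle is returned with
    ``cycle=True``.  Uncensored data converge in one step to OLS.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Xc = data.X - data.X.mean(axis=0)
    A = Xc.T @ Xc
    if np.linalg.matrix_rank(A) < data.p:  # pragma: no cover - blocked by validation
        raise np.linalg.LinAlgError("singular centered design")

    def update(b: np.ndarray) -> np.ndarray:
        return np.linalg.solve(A, Xc.T @ impute_responses(data, b))

    beta = (
        np.linalg.solve(A, Xc.T @ data.Z)
        if beta0 is None
        else _check_beta(beta0, data.p)
    )
    history = [beta]
    for k in range(1, max_iter + 1):
        beta_new = update(beta)
        if np.linalg.norm(beta_new - beta) <= tol:
            return BJFit(beta=beta_new, iterations=k, converged=True, cycle=False)
        window = history[-cycle_window:-1] if len(history) > 1 else []
        for back, old in enumerate(reversed(window), start=2):
            if np.linalg.norm(beta_new - old) <= tol:
                # beta_new revisits history[-back]: a cycle of period `back`
                avg = np.mean(history[-back:], axis=0)
                return BJFit(beta=avg, iterations=k, converged=False, cycle=True)
        history.append(beta_new)
        beta = beta_new
    return BJFit(beta=beta, iterations=max_iter, converged=False, cycle=False)
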