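"""Empirical likelihood with auxiliary covariate information E g(X) = 0.

Known population facts about the covariates -- a known mean, a known second
moment -- enter as extra moment constraints ``sum_i p_i g(X_i) = 0``
alongside the estimating-equation constraints.  Stacking

    A_i(beta) = ( g(X_i)' , W_i(beta)' )'

and solving the same EL inner problem over the (r + p)-column score matrix
gives the constrained log ratio ``l_AU``.  Its calibrating adjustment mixes
the auxiliary block (whose rows are genuinely i.i.d., so their naive second
moment is correct) with the martingale variance of the estimating-function
block:

    V1_AU = [[Vn1, Vn2], [Vn2', Sigma1]],   V2_AU = blockdiag(Vn1, Sigma2),
    c_AU  = tr(V2_AU^{-1} Psi) / tr(V1_AU^{-1} Psi),
    Psi   = (sum_i A_i)(sum_i A_i)',

and ``c_AU * l_AU`` is asymptotically chi-square with p + r degrees of
freedom at the true slope under a correctly specified constraint.  With no
constraints (r = 0) everything reduces exactly to the unaugmented test.

Constraint functions are user-supplied callables evaluated per covariate
row; a callable may instead accept the whole (n, p) matrix and return a
length-n vector (detected by shape), which avoids the per-row Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .buckley_james import estimating_function
from .data import CensoredRegressionData, _check_beta, residuals
from .el import el_solve
from .elee import (
    AdjustedTestResult,
    DegenerateDataError,
    _sigma2_from_parts,
    elee_test,
)
from .km import km_fit

__all__ = ["AuxELComponents", "aux_scores", "aux_el_test"]

ConstraintFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class AuxELComponents:
    """Stacked auxiliary + estimating-function scores and their block matrices."""

    A: np.ndarray  # (n, r + p)
    Vn1: np.ndarray  # (r, r)
    Vn2: np.ndarray  # (r, p)
    V1AU: np.ndarray  # (r + p, r + p)
    V2AU: np.ndarray  # (r + p, r + p)
    Psi: np.ndarray  # (r + p, r + p) rank-one
    cnAU: float
    r: int


def _evaluate_constraints(
    X: np.ndarray, g: Sequence[ConstraintFn]
) -> np.ndarray:
    n = X.shape[0]
    cols = []
    for gk in g:
        try:
            val = np.asarray(gk(X), dtype=float)
            if val.shape == (n,):
                cols.append(val)
                continue
        except Exception:
            pass
        cols.append(np.array([float(gk(row)) for row in X]))
    return np.column_stack(cols)


def aux_scores(
    data: CensoredRegressionData, beta, g: Sequence[ConstraintFn]
) -> AuxELComponents:
    """Assemble the stacked score rows and adjustment blocks at one slope."""
    if len(g) == 0:
        raise ValueError("need at least one constraint function; use elee_test for r=0")
    b = _check_beta(beta, data.p)
    n = data.n
    G = _evaluate_constraints(data.X, g)
    r = G.shape[1]
    Vn1 = G.T @ G / n
    cond = np.linalg.cond(Vn1)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDataError("constraint moment matrix Vn1 is (near) singular")

    W = estimating_function(data, b).W
    e = residuals(data, b)
    curve = km_fit(e, data.delta, largest_as_event=True)
    Sigma1 = W.T @ W / n
    Sigma2 = _sigma2_from_parts(data.X, e, data.delta, curve)

    A = np.hstack([G, W])
    Vn2 = G.T @ W / n
    p = data.p
    V1AU = np.zeros((r + p, r + p))
    V1AU[:r, :r] = Vn1
    V1AU[:r, r:] = Vn2
    V1AU[r:, :r] = Vn2.T
    V1AU[r:, r:] = Sigma1
    V2AU = np.zeros((r + p, r + p))
    V2AU[:r, :r] = Vn1
    V2AU[r:, r:] = Sigma2

    v = A.sum(axis=0)
    Psi = np.outer(v, v)
    try:
        q2 = float(v @ np.linalg.solve(V2AU, v))
        q1 = float(v @ np.linalg.solve(V1AU, v))
    except np.linalg.LinAlgError as err:
        raise DegenerateDataError(f"singular block matrix: {err}") from err
    if q1 <= 0.0:
        u1 = np.linalg.eigh(V1AU)[1][:, -1]
        q2 = float(u1 @ np.linalg.solve(V2AU, u1))
        q1 = float(u1 @ np.linalg.solve(V1AU, u1))
    cnAU = q2 / q1
    if not np.isfinite(cnAU) or cnAU <= 0.0:
        raise DegenerateDataError(f"auxiliary adjustment cnAU={cnAU} is not positive")
    return AuxELComponents(
        A=A, Vn1=Vn1, Vn2=Vn2, V1AU=V1AU, V2AU=V2AU, Psi=Psi, cnAU=cnAU, r=r
    )


def aux_el_test(
    data: CensoredRegressionData, beta0, g: Sequence[ConstraintFn]
) -> AdjustedTestResult:
    """Adjusted EL test of ``H0: beta = beta0`` under auxiliary constraints.

    With an empty constraint list this is exactly the unaugmented adjusted
    test (df = p); otherwise df = p + r.
    """
    if len(g) == 0:
        return elee_test(data, beta0)
    comp = aux_scores(data, beta0, g)
    sol = el_solve(comp.A)
    df = data.p + comp.r
    if not np.isfinite(sol.log_ratio):
        stat, p_value = np.inf, 0.0
    else:
        stat = comp.cnAU * sol.log_ratio
        p_value = float(stats.chi2.sf(stat, df=df))
    return AdjustedTestResult(
        ln=sol.log_ratio,
        cn=comp.cnAU,
        statistic=stat,
        df=df,
        p_value=p_value,
        status=sol.status,
    )
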