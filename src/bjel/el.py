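"""Owen-style empirical likelihood inner problem for an n x q score matrix.

Given score rows ``w_1, ..., w_n`` the empirical log-likelihood ratio for
the hypothesis that their common mean is zero is

    l = -2 max { sum_i log(n p_i) : sum_i p_i w_i = 0, sum_i p_i = 1, p_i >= 0 },

attained, when the origin is interior to the convex hull of the rows, at
``p_i = 1 / [n (1 + lam' w_i)]`` with the multiplier ``lam`` solving

    (1/n) sum_i w_i / (1 + lam' w_i) = 0,

so that ``l = 2 sum_i log(1 + lam' w_i)``.  The multiplier maximizes the
strictly concave dual ``sum_i log(1 + lam' w_i)`` over the open region where
every factor is positive.

Solver: damped Newton on the dual with step-halving backtracking that keeps
``1 + lam' w_i >= 1/n`` along the path (every weight stays <= 1 and the logs
finite); for a single constraint the multiplier is bracketed and solved by
bisection-safeguarded root finding.  No log-star smoothing is applied: the
statistic is the exact constrained log ratio.

A hull failure (origin outside the convex hull) maps to ``log_ratio = +inf``
rather than an exception, so confidence-region scans treat infeasible
candidate slopes as rejected at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, linprog

__all__ = ["ELSolution", "el_solve", "hull_contains_origin"]


@dataclass(frozen=True)
class ELSolution:
    """Solution of the EL inner problem for one score matrix.

    ``lam`` is the Lagrange multiplier, ``log_ratio`` the -2 log EL ratio
    (``+inf`` on hull failure), ``weights`` the per-row probabilities (None
    unless the solution is interior).
    """

    lam: np.ndarray | None
    log_ratio: float
    weights: np.ndarray | None
    status: str  # interior | hull_failure | not_converged
    n_iter: int = 0


def hull_contains_origin(scores) -> bool:
    """True iff the origin is interior to the convex hull of the score rows.

    For one column this is ``min < 0 < max``; for more columns a small linear
    feasibility problem looks for strictly positive convex weights averaging
    the rows to zero.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n, q = S.shape
    if q == 1:
        w = S[:, 0]
        return bool(w.min() < 0.0 < w.max())
    # scale columns for conditioning of the LP
    scale = np.maximum(np.abs(S).max(axis=0), 1e-300)
    A_eq = np.vstack([(S / scale).T, np.ones(n)])
    b_eq = np.r_[np.zeros(q), 1.0]
    res = linprog(
        c=np.zeros(n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(1e-9, 1.0)] * n,
        method="highs",
    )
    return bool(res.status == 0)


def _solve_q1(w: np.ndarray, n: int) -> tuple[float, int]:
    wmax, wmin = w.max(), w.min()
    lo, hi = -1.0 / wmax, -1.0 / wmin  # open interval with all 1 + lam*w > 0

    def g(lam: float) -> float:
        return float(np.sum(w / (1.0 + lam * w)))

    eps = 1e-10 * (hi - lo)
    for _ in range(40):
        a, b = lo + eps, hi - eps
        ga, gb = g(a), g(b)
        if ga > 0.0 > gb:
            return brentq(g, a, b, xtol=1e-14, rtol=8.9e-16, maxiter=200), 1
        if ga <= 0.0 and gb <= 0.0:
            eps *= 0.1  # move closer to the lower boundary
        elif ga >= 0.0 and gb >= 0.0:
            eps *= 0.1
        else:  # pragma: no cover - g is strictly decreasing
            break
        if eps <= 0.0:  # pragma: no cover
            break
    raise RuntimeError("failed to bracket the EL multiplier")  # pragma: no cover


def el_solve(scores, tol: float = 1e-10, max_iter: int = 50) -> ELSolution:
    """Solve the EL inner problem for a score matrix.

    Parameters
    ----------
    scores : (n, q) array
        Score rows; a 1-d array is treated as a single column.
    tol : float
        Convergence threshold on the constraint equation, relative to the
        typical score magnitude.
    max_iter : int
        Newton iteration cap (the one-dimensional bracketed solver ignores
        it).

    Raises
    ------
    numpy.linalg.LinAlgError
        If a score column is identically zero (the multiplier is then
        unidentified).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n, q = S.shape
    if n <= q:
        raise ValueError(f"need n > q score rows, got n={n}, q={q}")
    if not np.isfinite(S).all():
        raise ValueError("scores must be finite")
    if np.all(S == 0.0, axis=0).any():
        raise np.linalg.LinAlgError("degenerate scores: a column is identically zero")

    scale = max(float(np.abs(S).mean()), 1e-300)
    if not hull_contains_origin(S):
        return ELSolution(
            lam=None, log_ratio=np.inf, weights=None, status="hull_failure"
        )

    if q == 1:
        w = S[:, 0]
        lam_val, it = _solve_q1(w, n)
        lam = np.array([lam_val])
        d = 1.0 + w * lam_val
        return ELSolution(
            lam=lam,
            log_ratio=float(2.0 * np.log(d).sum()),
            weights=1.0 / (n * d),
            status="interior",
            n_iter=it,
        )

    # damped Newton on the concave dual, multipliers on scaled scores
    Ss = S / scale
    lam = np.zeros(q)
    d = np.ones(n)
    obj = 0.0
    status = "not_converged"
    it = 0
    for it in range(1, 4 * max_iter + 1):
        grad = (Ss / d[:, None]).sum(axis=0)
        if np.abs(grad).max() / n <= tol:
            status = "interior"
            break
        R = Ss / d[:, None]
        H = R.T @ R  # = sum_i w w' / d^2
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by zero-col check
            break
        t = 1.0
        accepted = False
        while t >= 1e-14:
            lam_try = lam + t * step
            d_try = 1.0 + Ss @ lam_try
            if (d_try >= 1.0 / n).all():
                obj_try = float(np.log(d_try).sum())
                if obj_try >= obj - 1e-14:
                    lam, d, obj = lam_try, d_try, obj_try
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
    else:  # pragma: no cover
        pass
    grad = (Ss / d[:, None]).sum(axis=0)
    if np.abs(grad).max() / n <= max(tol, 1e-8):
        status = "interior"
    return ELSolution(
        lam=lam / scale,
        log_ratio=float(2.0 * np.log(d).sum()),
        weights=1.0 / (n * d),
        status=status,
        n_iter=it,
    )
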