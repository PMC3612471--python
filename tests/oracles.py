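"""Independent brute-force oracles used only by the tests.

Everything here is written straight from the defining formulas with explicit
loops and no shared code with the package, so agreement is meaningful.
"""

import numpy as np
from scipy.optimize import minimize


def naive_km(values, events, largest_as_event=False):
    """Product-limit fit by direct looping over distinct sorted values.

    Returns (support, surv, jump_mass).  Events at a value are counted
    against the risk set of everything >= that value (censored ties
    included).
    """
    v = np.asarray(values, float)
    d = np.asarray(events, int).copy()
    if largest_as_event:
        d[v == v.max()] = 1
    support = np.unique(v)
    surv, jumps = [], []
    s = 1.0
    for t in support:
        at_risk = int((v >= t).sum())
        deaths = int(d[(v == t)].sum())
        s_new = s * (1.0 - deaths / at_risk)
        jumps.append(s - s_new)
        surv.append(s_new)
        s = s_new
    return support, np.array(surv), np.array(jumps)


def naive_tail_mean(support, jumps, u):
    """Conditional mean of the jump distribution strictly above u."""
    mask = support > u
    denom = jumps[mask].sum()
    if denom <= 0:
        raise ZeroDivisionError
    return float((support[mask] * jumps[mask]).sum() / denom)


def naive_estimating_function(X, Z, delta, beta):
    """Rows (X_i - Xbar) * [delta_i e_i + (1 - delta_i) E(e | e > e_i)]."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    beta = np.asarray(beta, float).ravel()
    e = np.asarray(Z, float) - X @ beta
    support, _, jumps = naive_km(e, delta, largest_as_event=True)
    xbar = X.mean(axis=0)
    rows = []
    for i in range(len(e)):
        if delta[i] == 1:
            r = e[i]
        else:
            try:
                r = naive_tail_mean(support, jumps, e[i])
            except ZeroDivisionError:
                r = support.max()
        rows.append((X[i] - xbar) * r)
    return np.array(rows)


def naive_sigma2(X, Z, delta, beta):
    """Martingale variance estimator summed term by term over events."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    n, p = X.shape
    beta = np.asarray(beta, float).ravel()
    e = np.asarray(Z, float) - X @ beta
    support, _, jumps = naive_km(e, delta, largest_as_event=True)
    total = np.zeros((p, p))
    for i in range(n):
        if delta[i] != 1:
            continue
        u = e[i]
        risk = e >= u
        nr = int(risk.sum())
        xbar_u = X[risk].mean(axis=0)
        V = np.zeros((p, p))
        for j in np.flatnonzero(risk):
            diff = X[j] - xbar_u
            V += np.outer(diff, diff)
        V /= nr
        try:
            m = naive_tail_mean(support, jumps, u)
        except ZeroDivisionError:
            m = u  # boundary event: zero deviation
        total += (u - m) ** 2 * V
    return total / n


def brute_force_el_log_ratio(scores):
    """-2 max sum log(n p_i) under the EL constraints, by direct optimization."""
    S = np.atleast_2d(np.asarray(scores, float))
    if S.shape[1] > S.shape[0]:
        S = S.T
    n, q = S.shape
    cons = [
        {"type": "eq", "fun": lambda p: p.sum() - 1.0},
        *[
            {"type": "eq", "fun": lambda p, j=j: p @ S[:, j]}
            for j in range(q)
        ],
    ]
    best = None
    for start in range(3):
        rng = np.random.default_rng(start)
        p0 = rng.dirichlet(np.ones(n)) if start else np.full(n, 1.0 / n)
        res = minimize(
            lambda p: -np.sum(np.log(n * p)),
            p0,
            constraints=cons,
            bounds=[(1e-12, 1.0)] * n,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best):
            best = res.fun
    if best is None:
        raise RuntimeError("brute-force EL optimization failed")
    return 2.0 * best
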