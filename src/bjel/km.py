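"""Product-limit (Kaplan-Meier) estimation with jump masses and tail means.

This module estimates two distributions that drive everything downstream:

* the residual error distribution ``F``, fitted to the residuals
  ``e_i(beta) = Z_i - X_i' beta`` with the event indicators ``delta_i`` --
  refit at every candidate slope, because the residuals move with ``beta``;
* the censoring survival function ``G``, fitted to ``Z`` with the flipped
  indicators ``1 - delta`` (censoring treated as the event).

Curves are stored as right-continuous step functions together with their
exact jump masses, so conditional tail means -- the Buckley-James imputation
kernel ``E[e | e > u]`` -- are a single reverse cumulative sum away.

Conventions (both configurable only by constructing the inputs accordingly):

* ties between an event and a censored observation at the same value rank
  the event first, i.e. the censored observation stays in the risk set for
  that event (the standard product-limit tie rule);
* ``largest_as_event=True`` applies Efron's tail completion: censored
  observations tied at the sample maximum are treated as events, which makes
  the fitted distribution proper (total mass 1) and every tail mean finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CensoredRegressionData

__all__ = [
    "KMCurve",
    "DegenerateTailError",
    "km_fit",
    "km_censoring_fit",
    "tail_mean",
    "tail_means",
    "eval_surv",
    "eval_surv_left",
]


class DegenerateTailError(ValueError):
    """No probability mass strictly above the requested threshold."""


@dataclass(frozen=True)
class KMCurve:
    """A product-limit estimate as a right-continuous step function.

    Attributes
    ----------
    support : (m,) array
        Sorted distinct observed values.
    surv : (m,) array
        Survival probabilities ``S(t_k)`` evaluated right-continuously.
    jump_mass : (m,) array
        Probability mass ``S(t_k-) - S(t_k)`` at each support point (zero at
        censored-only points).
    is_proper : bool
        True iff the total jump mass is 1 (terminal survival 0).
    """

    support: np.ndarray
    surv: np.ndarray
    jump_mass: np.ndarray
    is_proper: bool

    @property
    def total_mass(self) -> float:
        return float(self.jump_mass.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabulate (support, surv, jump_mass), e.g. for a debugging TSV dump."""
        return pd.DataFrame(
            {"support": self.support, "surv": self.surv, "jump_mass": self.jump_mass}
        )


def km_fit(
    values,
    events,
    largest_as_event: bool = False,
    tie_exit_first=None,
) -> KMCurve:
    """Kaplan-Meier product-limit fit of the distribution of ``values``.

    Parameters
    ----------
    values : (n,) array
        Observations (may be signed residuals).
    events : (n,) array of {0, 1}
        1 where the value is an observed event, 0 where censored.
    largest_as_event : bool
        Apply Efron's tail completion: censored observations at the sample
        maximum are counted as events so the curve is proper.
    tie_exit_first : (n,) bool array, optional
        Observations that leave the risk set *before* events occurring at the
        same value.  Used by :func:`km_censoring_fit`, where a death tied
        with a censoring time is ranked first and hence is no longer at risk
        for the censoring event.

    Ties among events at a common value are aggregated against the common
    risk set.
    """
    v = np.asarray(values, dtype=float).ravel()
    d = np.asarray(events).ravel().astype(np.int8)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != d.shape:
        raise ValueError("values and events must have equal length")
    n = v.size

    order = np.argsort(v, kind="stable")
    vs = v[order]
    ds = d[order].copy()
    if largest_as_event:
        ds[vs == vs[-1]] = 1

    first = np.r_[True, vs[1:] != vs[:-1]]
    starts = np.flatnonzero(first)
    support = vs[starts]
    counts = np.diff(np.r_[starts, n])
    deaths = np.add.reduceat(ds, starts)
    at_risk = n - np.r_[0, np.cumsum(counts)[:-1]]
    if tie_exit_first is not None:
        exits = np.asarray(tie_exit_first).ravel().astype(np.int8)[order]
        at_risk = at_risk - np.add.reduceat(exits, starts)

    with np.errstate(invalid="ignore", divide="ignore"):
        haz = np.where(at_risk > 0, deaths / np.maximum(at_risk, 1), 0.0)
    surv = np.cumprod(1.0 - haz)
    jump = np.maximum(np.r_[1.0, surv[:-1]] - surv, 0.0)
    is_proper = bool(abs(jump.sum() - 1.0) <= 1e-12)
    return KMCurve(support=support, surv=surv, jump_mass=jump, is_proper=is_proper)


def km_censoring_fit(data: CensoredRegressionData) -> KMCurve:
    """Product-limit estimate of the censoring survival function ``G``.

    Applies :func:`km_fit` to ``Z`` with indicators ``1 - delta``.  At a tie
    between a death and a censoring time the death is removed from the risk
    set first (the complement of the tie rule used for the residual
    distribution).  No tail completion: an improper censoring curve is
    expected and harmless.
    """
    return km_fit(
        data.Z,
        1 - data.delta,
        largest_as_event=False,
        tie_exit_first=data.delta == 1,
    )


def eval_surv(curve: KMCurve, t) -> np.ndarray | float:
    """Right-continuous survival value(s) ``S(t)``."""
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.support, t_arr, side="right")
    out = np.where(idx == 0, 1.0, curve.surv[np.maximum(idx - 1, 0)])
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def eval_surv_left(curve: KMCurve, t) -> np.ndarray | float:
    """Left-limit survival value(s) ``S(t-)``, just before ``t``."""
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.support, t_arr, side="left")
    out = np.where(idx == 0, 1.0, curve.surv[np.maximum(idx - 1, 0)])
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _tail_suffix_sums(curve: KMCurve) -> tuple[np.ndarray, np.ndarray]:
    mass = np.r_[np.cumsum(curve.jump_mass[::-1])[::-1], 0.0]
    moment = np.r_[np.cumsum((curve.support * curve.jump_mass)[::-1])[::-1], 0.0]
    return mass, moment


def tail_mean(curve: KMCurve, u: float) -> float:
    """Mean of the fitted distribution conditional on exceeding ``u``.

    Computes ``sum_{t_k > u} t_k m_k / sum_{t_k > u} m_k`` over the jump
    masses ``m_k``.  Raises :class:`DegenerateTailError` when no mass lies
    strictly above ``u`` (callers apply their documented fallback).
    """
    mass, moment = _tail_suffix_sums(curve)
    k = int(np.searchsorted(curve.support, u, side="right"))
    if mass[k] <= 0.0:
        raise DegenerateTailError(f"no probability mass above u={u}")
    return float(moment[k] / mass[k])


def tail_means(curve: KMCurve, us, fallback: str = "max_support") -> np.ndarray:
    """Vectorized :func:`tail_mean` with an explicit degenerate-tail fallback.

    Parameters
    ----------
    us : array
        Query points.
    fallback : {"max_support", "self"}
        Value to use where no mass lies strictly above the query point:
        the largest support point (Buckley-James imputation convention) or
        the query point itself (variance-estimator boundary convention,
        which zeroes the corresponding squared deviation).
    """
    u_arr = np.asarray(us, dtype=float).ravel()
    mass, moment = _tail_suffix_sums(curve)
    k = np.searchsorted(curve.support, u_arr, side="right")
    ok = mass[k] > 0.0
    out = np.empty_like(u_arr)
    out[ok] = moment[k[ok]] / mass[k[ok]]
    if fallback == "max_support":
        out[~ok] = curve.support[-1]
    elif fallback == "self":
        out[~ok] = u_arr[~ok]
    else:
        raise ValueError(f"unknown fallback {fallback!r}")
    return out
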