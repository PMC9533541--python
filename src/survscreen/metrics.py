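"""Prediction-performance metrics for survival models.

* Prognostic index PI_i = beta^T x_i — the linear risk score.
* Concordance index over comparable pairs: a pair is comparable when the
  patient with the shorter follow-up experienced the event (not censoring)
  and the two times differ. PI ties count 1/2.
* Time-dependent Brier score with inverse-probability-of-censoring
  weighting (IPCW), with the censoring distribution G estimated by
  Kaplan-Meier on the test split.
* Integrated Brier score: trapezoidal integral of BS(t) over the test
  split's event-time grid (augmented with 0 and t_max), divided by t_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SurvivalData, ValidationError

__all__ = [
    "prognostic_index",
    "ConcordanceResult",
    "concordance_index",
    "censoring_survival",
    "brier_score",
    "integrated_brier",
]


def prognostic_index(fit, X) -> np.ndarray:
    """PI = beta^T x per patient; invariant to zero-coefficient genes."""
    beta = fit.params if hasattr(fit, "params") else np.asarray(fit, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(beta):
        raise ValidationError(
            f"design has {X.shape[1]} covariates but fit has {len(beta)}"
        )
    return X @ beta


@dataclass
class ConcordanceResult:
    c_index: float          # nan when undefined
    n_comparable: int
    defined: bool

    def __iter__(self):  # allow tuple unpacking (c, n)
        yield self.c_index
        yield self.n_comparable


def concordance_index(pi: np.ndarray, data: SurvivalData) -> ConcordanceResult:
    """Harrell-style concordance over comparable pairs.

    C = (#concordant + 0.5 * #PI-ties) / #comparable, where a comparable
    pair has distinct times and the earlier time is an observed event.
    With zero comparable pairs the value is undefined (nan + flag), never a
    silent 0.5.
    """
    pi = np.asarray(pi, dtype=float)
    t, e = data.time, data.event
    n = len(t)
    if len(pi) != n:
        raise ValidationError("PI length must match survival data")
    # vectorized pair enumeration: i indexes the earlier, observed event
    conc = ties = comp = 0
    order = np.argsort(t, kind="stable")
    ts, es, ps = t[order], e[order], pi[order]
    for i in range(n - 1):
        if es[i] != 1:
            continue
        later = ts > ts[i]          # strictly later times only
        if not later.any():
            continue
        comp += int(later.sum())
        conc += int((ps[i] > ps[later]).sum())
        ties += int((ps[i] == ps[later]).sum())
    if comp == 0:
        return ConcordanceResult(float("nan"), 0, False)
    return ConcordanceResult((conc + 0.5 * ties) / comp, comp, True)


def censoring_survival(data: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Censoring events are the complement of the survival events. Returns
    (times, G) as a right-continuous step function starting at G(0) = 1.
    """
    t = data.time
    cens = 1 - data.event
    order = np.argsort(t, kind="stable")
    ts, cs = t[order], cens[order]
    uniq = np.unique(ts)
    at_risk = len(ts) - np.searchsorted(ts, uniq, side="left")
    d = np.array([cs[ts == u].sum() for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
    return uniq, np.cumprod(factors)


def _step_eval(times: np.ndarray, values: np.ndarray, at: np.ndarray,
               left_limit: bool = False) -> np.ndarray:
    """Evaluate the right-continuous step function (1 before first time)."""
    side = "left" if left_limit else "right"
    idx = np.searchsorted(times, np.asarray(at, float), side=side)
    padded = np.concatenate([[1.0], values])
    return padded[idx]


def brier_score(pred: np.ndarray, data: SurvivalData, t: float) -> float:
    """IPCW Brier score at time t.

    pred : predicted survival probability S(t | x_i) per test patient.
    Patients with an observed event before or at t contribute
    (0 - S)^2 / G(T_i^-); patients still at risk past t contribute
    (1 - S)^2 / G(t); patients censored before t contribute 0. G is the
    Kaplan-Meier censoring survival estimated on the same (test) data. If a
    needed G value is 0 the weight is truncated at the last positive value.
    """
    pred = np.asarray(pred, dtype=float)
    if t < 0:
        raise ValidationError("Brier time must be >= 0")
    if np.any((pred < 0) | (pred > 1)):
        raise ValidationError("predictions must be probabilities in [0, 1]")
    g_times, g_vals = censoring_survival(data)
    g_floor = g_vals[g_vals > 0].min() if np.any(g_vals > 0) else 1.0

    def g_at(at, left=False):
        g = _step_eval(g_times, g_vals, np.atleast_1d(at), left_limit=left)
        return np.maximum(g, g_floor)   # truncate at last positive G

    T, e = data.time, data.event
    event_before = (T <= t) & (e == 1)
    at_risk = T > t
    score = np.zeros(len(T))
    if event_before.any():
        score[event_before] = (pred[event_before] ** 2) / g_at(T[event_before], left=True)
    if at_risk.any():
        score[at_risk] = ((1.0 - pred[at_risk]) ** 2) / g_at(t)
    return float(score.mean())


def integrated_brier(pred_fn, data: SurvivalData) -> float:
    """Integrated Brier score over [0, t_max], t_max = max observed event time.

    pred_fn : callable t -> per-patient predicted S(t | x), or a
        (patients x grid) matrix paired with the grid produced by
        ``ibs_time_grid`` — pass a callable for clarity.
    The grid is the sorted unique event times augmented with 0 and t_max;
    the integral is trapezoidal and divided by t_max.
    """
    grid = ibs_time_grid(data)
    bs = np.array([brier_score(np.asarray(pred_fn(t), float), data, t) for t in grid])
    t_max = grid[-1]
    if t_max == 0:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / t_max)


def ibs_time_grid(data: SurvivalData) -> np.ndarray:
    """0, the sorted unique observed event times, and t_max."""
    ev = data.time[data.event == 1]
    if ev.size == 0:
        raise ValidationError("integrated Brier score needs at least one event")
    grid = np.unique(np.concatenate([[0.0], ev]))
    return grid
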