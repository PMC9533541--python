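"""Unpenalized Cox proportional-hazards machinery.

Breslow partial likelihood throughout (tied event times share the risk-set
denominator). The module provides a statsmodels-style ``CoxPH`` model whose
``fit()`` returns a :class:`CoxPHResults`, plus a vectorized single-gene
scan used by the supervised screening step: every gene gets its own
one-covariate Cox model, maximized by Newton iterations run in parallel
across genes, with a likelihood-ratio p-value against chi2(1).

Design matrices here are patients x covariates (the transpose of the
genes x patients expression layout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import SurvivalData, ValidationError

__all__ = [
    "CoxPH",
    "CoxPHResults",
    "BaselineHazard",
    "cox_partial_loglik",
    "fit_cox",
    "single_gene_fits",
    "single_gene_pvalues",
    "bh_adjust",
    "breslow_baseline",
    "predict_survival",
    "schoenfeld_test",
]

BETA_CAP = 20.0  # monotone-likelihood guard: |beta| beyond this flags divergence
MAX_ITER = 25
LOGLIK_TOL = 1e-9


# ---------------------------------------------------------------------------
# risk-set bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _RiskOrder:
    """Ascending-time ordering with anchors to the first index of each tie
    group; the risk set of an event at sorted position i is positions
    anchor[i]..n-1."""

    order: np.ndarray
    time: np.ndarray       # sorted
    event: np.ndarray      # sorted
    anchor: np.ndarray     # per sorted position, first index with same time
    event_pos: np.ndarray  # sorted positions that are events


def _risk_order(data: SurvivalData) -> _RiskOrder:
    if data.n_events < 1:
        raise ValidationError("at least one observed event is required")
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    new_group = np.concatenate([[True], t[1:] != t[:-1]])
    anchor = np.maximum.accumulate(np.where(new_group, np.arange(len(t)), 0))
    return _RiskOrder(order, t, e, anchor, np.flatnonzero(e == 1))


def _revcumsum(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


# ---------------------------------------------------------------------------
# partial likelihood, score, information (small-p exact Newton)
# ---------------------------------------------------------------------------

def cox_partial_loglik(
    beta: np.ndarray, X: np.ndarray, data: SurvivalData, offset: np.ndarray | None = None
) -> float:
    """Breslow log partial likelihood l(beta).

    At beta = 0 (no offset) this reduces to -sum over events of
    log(risk-set size).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(data):
        raise ValidationError("X rows must match number of patients")
    ro = _risk_order(data)
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    eta_s = eta[ro.order]
    w = np.exp(eta_s)
    s0 = _revcumsum(w)
    ep = ro.event_pos
    return float(eta_s[ep].sum() - np.log(s0[ro.anchor[ep]]).sum())


def _loglik_grad_info(beta, Xs, ro, offset_s=None):
    """loglik, score and information at beta on pre-sorted arrays."""
    eta = Xs @ beta
    if offset_s is not None:
        eta = eta + offset_s
    # guard overflow in exp for diverging fits
    w = np.exp(np.clip(eta, -500, 500))
    s0 = _revcumsum(w)
    s1 = _revcumsum(w[:, None] * Xs)
    xxt = Xs[:, :, None] * Xs[:, None, :]
    s2 = _revcumsum(w[:, None, None] * xxt)
    ep = ro.event_pos
    a = ro.anchor[ep]
    ll = float(eta[ep].sum() - np.log(s0[a]).sum())
    xbar = s1[a] / s0[a][:, None]
    grad = Xs[ep].sum(axis=0) - xbar.sum(axis=0)
    vbar = s2[a] / s0[a][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    info = vbar.sum(axis=0)
    return ll, grad, info


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard: step function over event times."""

    event_times: np.ndarray
    cumhaz: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.cumhaz = np.asarray(self.cumhaz, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValidationError("event times must be strictly increasing")
        if np.any(np.diff(self.cumhaz) < 0) or np.any(self.cumhaz < 0):
            raise ValidationError("cumulative hazard must be non-decreasing, >= 0")

    def at(self, times: np.ndarray) -> np.ndarray:
        """H0(t), right-continuous, 0 before the first event time."""
        idx = np.searchsorted(self.event_times, np.asarray(times, float), side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, likelihoods, convergence metadata."""

    params: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    bse: np.ndarray | None = None
    var_names: list[str] | None = None
    penalty: str | None = None
    model: "CoxPH | None" = field(default=None, repr=False)

    @property
    def lrt_statistic(self) -> float:
        return max(2.0 * (self.loglik - self.loglik_null), 0.0)

    def lrt_pvalue(self, df: int | None = None) -> float:
        df = df if df is not None else len(self.params)
        return float(stats.chi2.sf(self.lrt_statistic, df))

    def predict_pi(self, X_new: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X_new, float)) @ self.params

    def summary(self) -> str:
        import pandas as pd

        names = self.var_names or [f"x{j}" for j in range(len(self.params))]
        rows = {"coef": self.params}
        if self.bse is not None:
            z = np.divide(self.params, self.bse, out=np.zeros_like(self.params),
                          where=self.bse > 0)
            rows["se(coef)"] = self.bse
            rows["z"] = z
            rows["p"] = 2 * stats.norm.sf(np.abs(z))
        tbl = pd.DataFrame(rows, index=names)
        head = (
            f"Cox proportional hazards ({self.penalty or 'unpenalized'}, Breslow ties)\n"
            f"log partial likelihood: {self.loglik:.4f} (null {self.loglik_null:.4f})\n"
            f"converged: {self.converged} in {self.n_iter} iterations\n"
        )
        return head + tbl.to_string(float_format=lambda v: f"{v:.4f}")


class CoxPH:
    """Cox proportional-hazards model (unpenalized, small p).

    Parameters
    ----------
    X : array, patients x covariates
    data : SurvivalData
    offset : optional per-patient linear offset held fixed during fitting
    """

    def __init__(self, X, data: SurvivalData, var_names=None, offset=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(data):
            raise ValidationError("X rows must match number of patients")
        self.data = data
        self.var_names = list(var_names) if var_names is not None else None
        self.offset = None if offset is None else np.asarray(offset, dtype=float)

    def fit(self) -> CoxPHResults:
        """Newton-Raphson with step-halving; divergence (monotone likelihood)
        is capped at |beta| = 20 and flagged, not raised."""
        ro = _risk_order(self.data)
        Xs = self.X[ro.order]
        off_s = self.offset[ro.order] if self.offset is not None else None
        p = Xs.shape[1]
        beta = np.zeros(p)
        ll, grad, info = _loglik_grad_info(beta, Xs, ro, off_s)
        ll0 = ll
        converged = False
        diverged = False
        it = 0
        for it in range(1, MAX_ITER + 1):
            try:
                step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
            except np.linalg.LinAlgError:
                step = grad / (np.trace(info) / p + 1e-12)
            # step-halving on the partial likelihood
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                ll_new, g_new, i_new = _loglik_grad_info(cand, Xs, ro, off_s)
                if ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            beta, delta = cand, ll_new - ll
            ll, grad, info = ll_new, g_new, i_new
            if np.any(np.abs(beta) > BETA_CAP):
                beta = np.clip(beta, -BETA_CAP, BETA_CAP)
                ll, grad, info = _loglik_grad_info(beta, Xs, ro, off_s)
                diverged = True
                break
            if abs(delta) < LOGLIK_TOL:
                converged = True
                break
        bse = None
        if not diverged:
            try:
                bse = np.sqrt(np.diag(np.linalg.inv(info)))
            except np.linalg.LinAlgError:
                bse = None
        return CoxPHResults(
            params=beta,
            loglik=ll,
            loglik_null=ll0,
            n_iter=it,
            converged=converged and not diverged,
            bse=bse,
            var_names=self.var_names,
            model=self,
        )


def fit_cox(X, data: SurvivalData, offset=None) -> CoxPHResults:
    """Functional wrapper around :class:`CoxPH`."""
    return CoxPH(X, data, offset=offset).fit()


# ---------------------------------------------------------------------------
# vectorized single-gene scan
# ---------------------------------------------------------------------------

def single_gene_fits(
    values: np.ndarray,
    data: SurvivalData,
    offset: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
):
    """One-covariate Cox fit per gene, Newton iterations vectorized across genes.

    Parameters
    ----------
    values : genes x patients expression (standardized recommended)
    offset : optional fixed per-patient linear predictor (used by ISIS for
        conditional contributions)

    Returns
    -------
    beta : per-gene coefficient (capped at +-20 on divergence)
    loglik : per-gene maximized log partial likelihood
    loglik_null : scalar l(0) shared by all genes (offset-adjusted when given)
    converged : per-gene flag (False = divergence cap or iteration limit)
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes = values.shape[0]
    ro = _risk_order(data)
    X = values.T[ro.order]                      # n x g, sorted by time
    off_s = offset[ro.order][:, None] if offset is not None else None
    ep = ro.event_pos
    anch = ro.anchor[ep]

    def _loglik_cols(Xa, Ba):
        eta = Xa * Ba[None, :]
        if off_s is not None:
            eta = eta + off_s
        eta = np.clip(eta, -500, 500)
        s0 = _revcumsum(np.exp(eta))
        return eta[ep].sum(axis=0) - np.log(s0[anch]).sum(axis=0)

    # null log-likelihood (shared across genes; offset enters if given)
    eta0 = off_s[:, 0] if off_s is not None else np.zeros(X.shape[0])
    s0_null = _revcumsum(np.exp(np.clip(eta0, -500, 500)))
    ll0 = float(eta0[ep].sum() - np.log(s0_null[anch]).sum())

    B = np.zeros(n_genes)
    ll = np.full(n_genes, ll0)
    active = np.ones(n_genes, dtype=bool)
    diverged = np.zeros(n_genes, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xa, Ba = X[:, idx], B[idx]
        eta = Xa * Ba[None, :]
        if off_s is not None:
            eta = eta + off_s
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wx = w * Xa
        s0 = _revcumsum(w)
        s1 = _revcumsum(wx)
        s2 = _revcumsum(wx * Xa)
        xbar = s1[anch] / s0[anch]
        grad = Xa[ep].sum(axis=0) - xbar.sum(axis=0)
        hess = np.maximum((s2[anch] / s0[anch] - xbar**2).sum(axis=0), 1e-10)
        step = grad / hess
        # vectorized step-halving on the likelihood
        factor = np.ones(len(idx))
        ll_old = ll[idx]
        for _h in range(30):
            cand = np.clip(Ba + factor * step, -BETA_CAP, BETA_CAP)
            ll_new = _loglik_cols(Xa, cand)
            bad = ll_new < ll_old - 1e-12
            if not bad.any():
                break
            factor[bad] /= 2.0
        B[idx] = cand
        ll[idx] = ll_new
        at_cap = np.abs(cand) >= BETA_CAP - 1e-12
        diverged[idx[at_cap]] = True
        done = (np.abs(ll_new - ll_old) < LOGLIK_TOL) | at_cap
        active[idx[done]] = False

    converged = ~diverged & ~active
    return B, ll, ll0, converged


def single_gene_pvalues(
    expr, data: SurvivalData, offset: np.ndarray | None = None
) -> "pd.DataFrame":
    """Likelihood-ratio p-value of the single-variable Cox model per gene.

    Accepts an ExpressionMatrix (standardized expected; warns otherwise) or a
    raw genes x patients array. Genes whose fit fails get the conservative
    sentinel p = 1 and are counted in the returned frame's ``failed`` attr.
    Diverged (capped) fits keep the likelihood at the cap, which still yields
    a valid conservative LRT p-value.
    """
    import pandas as pd

    if hasattr(expr, "transform_tag"):
        if expr.transform_tag != "standardized":
            warnings.warn(
                "single-gene scan expects standardized expression; got "
                f"{expr.transform_tag!r}", stacklevel=2,
            )
        values = expr.values
        gene_ids = expr.gene_ids
    else:
        values = np.atleast_2d(np.asarray(expr, dtype=float))
        gene_ids = np.array([f"g{i}" for i in range(values.shape[0])], dtype=object)

    beta, ll, ll0, converged = single_gene_fits(values, data, offset=offset)
    lrt = np.maximum(2.0 * (ll - ll0), 0.0)
    p = stats.chi2.sf(lrt, 1)
    failed = ~np.isfinite(p)
    if failed.any():
        warnings.warn(f"{int(failed.sum())} gene fits failed; p set to 1", stacklevel=2)
        p = np.where(failed, 1.0, p)
        beta = np.where(failed, 0.0, beta)
    out = pd.DataFrame(
        {"gene_id": gene_ids, "beta": beta, "p": p, "p_adj": bh_adjust(p),
         "converged": converged}
    )
    out.attrs["failed"] = int(failed.sum())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# baseline hazard & survival prediction
# ---------------------------------------------------------------------------

def breslow_baseline(fit: CoxPHResults, X, data: SurvivalData) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard:
    H0(t) = sum over event times t_k <= t of d_k / sum_{risk set} exp(PI)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ fit.params
    ro = _risk_order(data)
    eta_s = np.clip(eta[ro.order], -500, 500)
    w = np.exp(eta_s)
    s0 = _revcumsum(w)
    ep = ro.event_pos
    anch = ro.anchor[ep]
    ev_times = ro.time[ep]
    uniq, first = np.unique(ev_times, return_index=True)
    d = np.bincount(np.searchsorted(uniq, ev_times), minlength=len(uniq))
    increments = d / s0[anch[first]]
    return BaselineHazard(uniq, np.cumsum(increments))


def predict_survival(
    fit: CoxPHResults, baseline: BaselineHazard, X_new, times
) -> np.ndarray:
    """S(t | x) = exp(-H0(t) * exp(PI)), patients x times, non-increasing in t."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValidationError("prediction times must be >= 0")
    pi = np.clip(fit.predict_pi(X_new), -500, 500)
    h0 = baseline.at(times)
    return np.exp(-np.outer(np.exp(pi), h0))


# ---------------------------------------------------------------------------
# proportional-hazards (Schoenfeld) test
# ---------------------------------------------------------------------------

def schoenfeld_test(beta, X, data: SurvivalData) -> float:
    """Global Grambsch-Therneau test of proportional hazards.

    Schoenfeld residuals are computed at the supplied (possibly penalized)
    coefficient vector treated as fixed; the global chi-square statistic
    tests association between residuals and event time with the identity
    time transform g(t) = t. Returns the p-value.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ro = _risk_order(data)
    if len(ro.event_pos) < 2:
        raise ValidationError("Schoenfeld test needs at least 2 events")
    Xs = X[ro.order]
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    s0 = _revcumsum(w)
    s1 = _revcumsum(w[:, None] * Xs)
    s2 = _revcumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))
    ep = ro.event_pos
    anch = ro.anchor[ep]
    xbar = s1[anch] / s0[anch][:, None]
    resid = Xs[ep] - xbar                       # events x p
    vbar = s2[anch] / s0[anch][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    g = ro.time[ep]
    gc = g - g.mean()
    d = (gc[:, None] * resid).sum(axis=0)
    D = (gc[:, None, None] ** 2 * vbar).sum(axis=0)
    p_dim = len(beta)
    try:
        stat = float(d @ np.linalg.solve(D + 1e-12 * np.eye(p_dim), d))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(stat, p_dim))
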