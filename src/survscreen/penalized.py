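"""Penalized Cox regression: ridge, lasso, elastic net, adaptive elastic net,
MCP and SCAD.

The engine is glmnet-style: an outer IRLS loop builds a weighted
least-squares approximation to the Breslow partial likelihood (objective
scaled as l(beta)/n minus the penalty), and cyclic coordinate descent with
an active-set strategy solves each approximation. The lambda path uses the
conventional construction lambda_max = max_j |grad_j l(0)/n| / max(alpha,
1e-3), 100 log-spaced values down to 0.01 * lambda_max, with warm starts.
Lambda is selected by minimizing the cross-validated partial-likelihood
deviance -2 * [l_full(beta_{-k}) - l_{-k}(beta_{-k})].

Ridge is fitted as the elastic net at alpha = 0 (penalty lambda/2 ||b||^2);
the lasso is alpha = 1. The adaptive elastic net is the two-step procedure:
a CV-selected ridge fit provides weights w_j = 1/|beta0_j| for a weighted
elastic-net second step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._cd import KIND_EN, KIND_MCP, KIND_SCAD, cd_solve
from .containers import SurvivalData, ValidationError
from .coxph import CoxPHResults, _revcumsum, _risk_order

__all__ = [
    "PenaltySpec",
    "LambdaPath",
    "PenalizedCox",
    "PenalizedCoxResults",
    "lambda_path",
    "fit_penalized",
    "adaptive_weights",
    "cv_select_lambda",
    "fit_penalized_cv",
    "kkt_check",
]

CD_TOL = 1e-7
KKT_TOL = 1e-4
WEIGHT_CAP = 1e6

_KINDS = ("ridge", "lasso", "en", "aen", "mcp", "scad")


@dataclass
class PenaltySpec:
    """Description of a penalty: kind, mixing weight, concavity, weights."""

    kind: str = "lasso"
    alpha: float | None = None
    gamma: float | None = None
    weights: np.ndarray | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown penalty kind {self.kind!r}")
        if self.alpha is None:
            self.alpha = {"ridge": 0.0, "lasso": 1.0}.get(self.kind, 0.5)
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.kind == "ridge" and self.alpha != 0.0:
            raise ValidationError("ridge requires alpha = 0")
        if self.kind == "lasso" and self.alpha != 1.0:
            raise ValidationError("lasso requires alpha = 1")
        if self.gamma is None:
            self.gamma = {"mcp": 3.0, "scad": 3.7}.get(self.kind, 0.0)
        if self.kind == "mcp" and self.gamma <= 1:
            raise ValidationError("MCP needs gamma > 1")
        if self.kind == "scad" and self.gamma <= 2:
            raise ValidationError("SCAD needs gamma > 2")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValidationError("penalty weights must be > 0")

    @property
    def engine_kind(self) -> int:
        return {"mcp": KIND_MCP, "scad": KIND_SCAD}.get(self.kind, KIND_EN)

    @property
    def is_convex(self) -> bool:
        return self.kind not in ("mcp", "scad")

    def pen_weights(self, p: int) -> np.ndarray:
        if self.weights is None:
            return np.ones(p)
        if len(self.weights) != p:
            raise ValidationError("penalty weights length mismatch")
        return self.weights


@dataclass
class LambdaPath:
    lambdas: np.ndarray
    n_nonzero: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValidationError("lambda path must be strictly decreasing")


@dataclass
class PenalizedCoxResults(CoxPHResults):
    """Penalized fit: coefficients at one lambda plus path diagnostics."""

    lam: float = 0.0
    spec: PenaltySpec | None = None
    kkt_violation: float | None = None
    path: LambdaPath | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.params))

    def summary(self) -> str:
        base = super().summary()
        extra = (
            f"\npenalty: {self.spec.kind if self.spec else '?'}, lambda = {self.lam:.5g}, "
            f"nonzero coefficients: {self.n_nonzero}"
        )
        if self.kkt_violation is not None:
            extra += f", max KKT violation: {self.kkt_violation:.2e}"
        return base + extra


# ---------------------------------------------------------------------------
# IRLS quantities for the Breslow partial likelihood
# ---------------------------------------------------------------------------

def _cox_irls(eta: np.ndarray, ro) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Return (loglik, per-patient score residual, IRLS weight, working
    response), all in original patient order."""
    n = len(eta)
    eta_s = np.clip(eta[ro.order], -500, 500)
    ex = np.exp(eta_s)
    s0 = _revcumsum(ex)
    ep = ro.event_pos
    anch_e = ro.anchor[ep]
    ll = float(eta_s[ep].sum() - np.log(s0[anch_e]).sum())

    contrib = np.zeros(n)
    contrib2 = np.zeros(n)
    np.add.at(contrib, ep, 1.0 / s0[anch_e])
    np.add.at(contrib2, ep, 1.0 / s0[anch_e] ** 2)
    cs, cs2 = np.cumsum(contrib), np.cumsum(contrib2)
    # cumulative hazard terms must include events tied with t_i
    uniq_anchor, inv = np.unique(ro.anchor, return_inverse=True)
    group_last = np.concatenate([uniq_anchor[1:] - 1, [n - 1]])
    last = group_last[inv]
    ch, ch2 = cs[last], cs2[last]

    grad_s = ro.event - ex * ch
    w_s = np.maximum(ex * ch - ex**2 * ch2, 0.0)
    z_s = np.where(w_s > 1e-10, eta_s + grad_s / np.maximum(w_s, 1e-10), eta_s)

    grad = np.empty(n); grad[ro.order] = grad_s
    w = np.empty(n); w[ro.order] = w_s
    z = np.empty(n); z[ro.order] = z_s
    return ll, grad, w, z


def _penalty_value(beta: np.ndarray, spec: PenaltySpec, lam: float, pw: np.ndarray) -> float:
    ab = np.abs(beta)
    if spec.engine_kind == KIND_EN:
        return float(lam * np.sum(pw * (spec.alpha * ab + (1 - spec.alpha) / 2 * beta**2)))
    g = spec.gamma
    if spec.engine_kind == KIND_MCP:
        per = np.where(ab <= g * lam, lam * ab - ab**2 / (2 * g), g * lam**2 / 2)
    else:  # SCAD
        per = np.where(
            ab <= lam,
            lam * ab,
            np.where(
                ab <= g * lam,
                (2 * g * lam * ab - ab**2 - lam**2) / (2 * (g - 1)),
                (g + 1) * lam**2 / 2,
            ),
        )
    return float(np.sum(pw * per))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _kkt_from_score(g: np.ndarray, beta: np.ndarray, spec: PenaltySpec,
                    lam: float, pw: np.ndarray) -> float:
    """Max elastic-net subgradient violation given the score g = grad l/n."""
    smooth = g - lam * (1 - spec.alpha) * pw * beta
    l1 = lam * spec.alpha * pw
    zero = beta == 0
    worst = 0.0
    if zero.any():
        worst = max(worst, float(np.max(np.abs(smooth[zero]) - l1[zero], initial=-np.inf)))
    act = ~zero
    if act.any():
        worst = max(
            worst, float(np.max(np.abs(smooth[act] - l1[act] * np.sign(beta[act]))))
        )
    return max(worst, 0.0)


def fit_penalized(
    X,
    data: SurvivalData,
    spec: PenaltySpec,
    lam: float,
    beta0: np.ndarray | None = None,
    max_outer: int = 50,
    max_sweeps: int = 200,
    var_names=None,
    warn_kkt: bool = True,
) -> PenalizedCoxResults:
    """Fit the penalized Cox model at a single lambda.

    X is expected standardized (patients x genes). For convex penalties the
    IRLS loop runs until the KKT conditions hold at tolerance 1e-4 (checked
    from the exact partial-likelihood score each iteration); non-convergence
    is flagged on the results, never raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    ro = _risk_order(data)
    n, p = X.shape
    if p == 0:
        ll0 = float(-np.log(_revcumsum(np.ones(n))[ro.anchor[ro.event_pos]]).sum())
        return PenalizedCoxResults(
            params=np.zeros(0), loglik=ll0, loglik_null=ll0, n_iter=0,
            converged=True, penalty=spec.kind, lam=lam, spec=spec, kkt_violation=0.0,
        )
    Xf = np.asfortranarray(X)
    pw = spec.pen_weights(p)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    ll, grad, w, z = _cox_irls(Xf @ beta, ro)
    ll0 = _cox_irls(np.zeros(n), ro)[0]
    obj = ll / n - _penalty_value(beta, spec, lam, pw)
    converged = False
    kkt = None
    it = 0
    for it in range(1, max_outer + 1):
        beta_prev = beta.copy()
        a = (w @ (Xf**2)) / n
        r = z - Xf @ beta
        cd_solve(
            Xf, w, r, a, beta, lam, spec.alpha, pw, spec.engine_kind, spec.gamma,
            CD_TOL, max_sweeps,
        )
        ll, grad, w, z = _cox_irls(Xf @ beta, ro)
        obj_new = ll / n - _penalty_value(beta, spec, lam, pw)
        if spec.is_convex and obj_new < obj - 1e-10:
            # step-halving toward the previous iterate
            for _ in range(10):
                beta = (beta + beta_prev) / 2.0
                ll, grad, w, z = _cox_irls(Xf @ beta, ro)
                obj_new = ll / n - _penalty_value(beta, spec, lam, pw)
                if obj_new >= obj - 1e-10:
                    break
        delta_obj, obj = obj_new - obj, obj_new
        if spec.is_convex:
            kkt = _kkt_from_score(Xf.T @ grad / n, beta, spec, lam, pw)
            # stop tolerance scales down with lambda so the unpenalized
            # limit converges to Newton accuracy
            if kkt < max(1e-6, min(KKT_TOL, lam * 1e-3)):
                converged = True
                break
            # saturated fits can stall below statistical precision: accept
            # once neither the objective nor the coefficients move
            if abs(delta_obj) < 1e-12 and np.max(np.abs(beta - beta_prev)) < CD_TOL:
                break
        else:
            if np.max(np.abs(beta - beta_prev)) < 1e-6 and abs(delta_obj) < 1e-9:
                converged = True
                break
    if spec.is_convex and warn_kkt and kkt is not None and kkt > 10 * KKT_TOL:
        warnings.warn(f"KKT violation {kkt:.2e} exceeds tolerance", stacklevel=2)
    return PenalizedCoxResults(
        params=beta, loglik=ll, loglik_null=ll0, n_iter=it, converged=converged,
        penalty=spec.kind, var_names=var_names, lam=lam, spec=spec, kkt_violation=kkt,
    )


def kkt_check(X, data: SurvivalData, beta, spec: PenaltySpec, lam: float) -> float:
    """Maximum violation of the elastic-net subgradient conditions at beta.

    For zero coefficients |grad_j| must not exceed lambda*alpha*pw_j; for
    active ones grad_j - lambda*(1-alpha)*pw_j*beta_j must equal
    lambda*alpha*pw_j*sign(beta_j), with grad the gradient of l/n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    ro = _risk_order(data)
    n, p = X.shape
    _, score, _, _ = _cox_irls(X @ beta, ro)
    g = X.T @ score / n
    pw = spec.pen_weights(p)
    smooth = g - lam * (1 - spec.alpha) * pw * beta
    l1 = lam * spec.alpha * pw
    zero = beta == 0
    viol_zero = np.maximum(np.abs(smooth[zero]) - l1[zero], 0.0)
    viol_act = np.abs(smooth[~zero] - l1[~zero] * np.sign(beta[~zero]))
    worst = 0.0
    if viol_zero.size:
        worst = max(worst, float(viol_zero.max()))
    if viol_act.size:
        worst = max(worst, float(viol_act.max()))
    return worst


def lambda_path(
    X,
    data: SurvivalData,
    spec: PenaltySpec,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
) -> LambdaPath:
    """Log-spaced lambda sequence from lambda_max down to
    lambda_min_ratio * lambda_max.

    lambda_max = max_j |grad_j l(0)/n / pw_j| / max(alpha, 1e-3); at this
    value every l1-penalized coefficient is exactly zero (KKT at the
    origin). The 1e-3 floor keeps the ridge path finite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ro = _risk_order(data)
    n, p = X.shape
    _, score, _, _ = _cox_irls(np.zeros(n), ro)
    g = X.T @ score / n
    pw = spec.pen_weights(p)
    lam_max = float(np.max(np.abs(g / pw)) / max(spec.alpha, 1e-3))
    if lam_max <= 0 or not np.isfinite(lam_max):
        lam_max = 1.0
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas)
    return LambdaPath(lambdas)


def path_fit(
    X, data: SurvivalData, spec: PenaltySpec, lambdas: np.ndarray,
    dfmax: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Warm-started fits along a decreasing lambda sequence.

    ``dfmax`` truncates the path once the active set exceeds it (the
    saturated small-lambda tail is expensive and never wins the deviance
    comparison); ``n_fitted`` reports how many path points were fitted.
    Returns (betas: L x p, n_nonzero: L, n_fitted).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    n_fitted = 0
    for i, lam in enumerate(lambdas):
        res = fit_penalized(X, data, spec, lam, beta0=beta, max_outer=25,
                            warn_kkt=False)
        beta = res.params
        betas[i] = beta
        n_fitted = i + 1
        if dfmax is not None and res.n_nonzero > dfmax:
            break
    return betas, np.count_nonzero(betas, axis=1), n_fitted


def adaptive_weights(ridge_fit: CoxPHResults | np.ndarray) -> np.ndarray:
    """Adaptive elastic-net weights w_j = 1 / |beta0_j| from a first-step
    ridge fit, capped at 1e6 for |beta0_j| < 1e-6."""
    beta0 = ridge_fit.params if hasattr(ridge_fit, "params") else np.asarray(ridge_fit)
    ab = np.abs(np.asarray(beta0, dtype=float))
    return np.where(ab < 1e-6, WEIGHT_CAP, 1.0 / np.maximum(ab, 1e-300))


def _stratified_folds(event: np.ndarray, k: int, seed: int):
    """Event-stratified K folds; re-drawn (new seed) until every training
    part has at least one event. Raises after 5 failures."""
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(event)), event))
        if all(event[tr].sum() >= 1 for tr, _ in folds):
            return folds
    raise ValidationError("could not build event-stratified folds")


def cv_select_lambda(
    X,
    data: SurvivalData,
    spec: PenaltySpec,
    K_inner: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
) -> tuple[float, PenalizedCoxResults, LambdaPath]:
    """Select lambda by minimizing the cross-validated partial-likelihood
    deviance, then refit on all data at the optimum.

    The per-fold deviance contribution is -2 * [l_full(beta_{-k}) -
    l_{-k}(beta_{-k})] (the cross-validated partial-likelihood form, robust
    to small test folds). Ties on the deviance go to the larger lambda
    (sparser model).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == 0:
        res = fit_penalized(X, data, spec, 0.0)
        return 0.0, res, LambdaPath(np.array([1.0, 0.5]))
    path = lambda_path(X, data, spec, n_lambdas, lambda_min_ratio)
    k = min(K_inner, int(data.n_events))
    if k < 2:
        raise ValidationError("not enough events for inner cross-validation")
    folds = _stratified_folds(data.event, k, seed)
    ro_full = _risk_order(data)
    dev = np.zeros(len(path.lambdas))
    n_valid = len(path.lambdas)
    for tr_idx, _ in folds:
        sub = data.subset(tr_idx)
        betas, _, n_fit = path_fit(
            X[tr_idx], sub, spec, path.lambdas, dfmax=max(10, sub.n_events)
        )
        n_valid = min(n_valid, n_fit)
        ro_sub = _risk_order(sub)
        for i in range(n_fit):
            beta = betas[i]
            ll_full = _cox_irls(X @ beta, ro_full)[0]
            ll_sub = _cox_irls(X[tr_idx] @ beta, ro_sub)[0]
            dev[i] += -2.0 * (ll_full - ll_sub)
    best = int(np.argmin(dev[:n_valid]))  # first (largest lambda) on ties
    betas_full, nnz, _ = path_fit(X, data, spec, path.lambdas[: best + 1])
    res = fit_penalized(
        X, data, spec, path.lambdas[best],
        beta0=betas_full[-1] if len(betas_full) else None,
    )
    full_nnz = np.concatenate([nnz, np.full(len(path.lambdas) - best - 1, -1)])
    out_path = LambdaPath(
        path.lambdas, n_nonzero=full_nnz, cv_deviance=np.where(
            np.arange(len(dev)) < n_valid, dev, np.nan)
    )
    res.path = out_path
    return float(path.lambdas[best]), res, out_path


def fit_penalized_cv(
    X,
    data: SurvivalData,
    spec: PenaltySpec,
    K_inner: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> PenalizedCoxResults:
    """One-stop CV fit dispatching the two-step adaptive elastic net.

    For kind="aen" with no explicit weights, a CV-selected ridge fit
    provides adaptive weights before the weighted elastic-net step.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if spec.kind == "aen" and spec.weights is None:
        ridge = PenaltySpec(kind="ridge")
        _, ridge_res, _ = cv_select_lambda(
            X, data, ridge, K_inner=K_inner, seed=seed + 1, n_lambdas=n_lambdas
        )
        spec = PenaltySpec(
            kind="aen", alpha=spec.alpha, weights=adaptive_weights(ridge_res)
        )
    if spec.lam is not None:
        return fit_penalized(X, data, spec, spec.lam)
    _, res, _ = cv_select_lambda(
        X, data, spec, K_inner=K_inner, seed=seed, n_lambdas=n_lambdas
    )
    return res


class PenalizedCox:
    """statsmodels-style front end: model object holding data and penalty;
    ``fit`` returns :class:`PenalizedCoxResults`.

    >>> model = PenalizedCox(X, survival, PenaltySpec("lasso"))
    >>> res = model.fit(seed=1)     # CV-selected lambda
    >>> res2 = model.fit(lam=0.1)   # fixed lambda
    """

    def __init__(self, X, data: SurvivalData, penalty: PenaltySpec | str = "lasso",
                 var_names=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(data):
            raise ValidationError("X rows must match number of patients")
        self.data = data
        self.penalty = PenaltySpec(penalty) if isinstance(penalty, str) else penalty
        self.var_names = var_names

    def fit(self, lam: float | None = None, K_inner: int = 5, seed: int = 0,
            n_lambdas: int = 100) -> PenalizedCoxResults:
        if lam is not None:
            res = fit_penalized(self.X, self.data, self.penalty, lam,
                                var_names=self.var_names)
        else:
            res = fit_penalized_cv(self.X, self.data, self.penalty,
                                   K_inner=K_inner, seed=seed, n_lambdas=n_lambdas)
            res.var_names = self.var_names
        res.model = self
        return res

    def lambda_path(self, n_lambdas: int = 100, lambda_min_ratio: float = 0.01):
        return lambda_path(self.X, self.data, self.penalty, n_lambdas, lambda_min_ratio)
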