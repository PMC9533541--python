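"""Gene pre-screening strategies.

The headline procedure is bi-dimensional screening: keep a gene only if its
BH-adjusted single-variable Cox p-value is at or below a supervised
threshold AND the IQR of its variance-stabilized expression is at or above
an unsupervised threshold. Threshold pairs come from fixed grids; the pair
(p = 1, IQR = 0) disables both screens. Alternatives provided for
comparison: top-k selection on raw p-values, a greedy correlation
pre-filter, and (iterative) sure independence screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, SurvivalData, ValidationError
from .coxph import single_gene_fits
from .penalized import PenaltySpec, fit_penalized_cv

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "iqr_scores",
    "bidimensional_screen",
    "topk_screen",
    "correlation_prefilter",
    "sis_rank",
    "sis_default_d",
    "isis_screen",
    "IsisResult",
]

DEFAULT_P_GRID = (0.01, 0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_IQR_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass
class ScreenConfig:
    """Threshold grids for the bi-dimensional screen plus optional top-k /
    ISIS settings."""

    p_grid: tuple = DEFAULT_P_GRID
    iqr_grid: tuple = DEFAULT_IQR_GRID
    topk: int | None = None
    isis_d: int | None = None

    def __post_init__(self) -> None:
        if list(self.p_grid) != sorted(self.p_grid) or list(self.iqr_grid) != sorted(
            self.iqr_grid
        ):
            raise ValidationError("threshold grids must be sorted ascending")
        if any(not 0 <= p <= 1 for p in self.p_grid):
            raise ValidationError("p-value thresholds must lie in [0, 1]")
        if any(q < 0 for q in self.iqr_grid):
            raise ValidationError("IQR thresholds must be >= 0")


@dataclass
class ScreenResult:
    """Per-gene screening statistics and the kept-gene mask for one
    threshold pair."""

    gene_ids: np.ndarray
    p_adj: np.ndarray
    iqr: np.ndarray
    mask: np.ndarray
    thresholds: tuple[float, float]

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())


def iqr_scores(expr: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Per-gene interquartile range (75th - 25th percentile, linear
    interpolation between order statistics).

    Expects VST-transformed expression (warns otherwise): on raw or log
    counts the IQR tracks the median, so thresholding would penalize low or
    high expressors rather than genuinely stable genes.
    """
    if hasattr(expr, "transform_tag"):
        if expr.transform_tag != "vst":
            warnings.warn(
                f"IQR screening expects VST expression, got {expr.transform_tag!r}",
                stacklevel=2,
            )
        values = expr.values
    else:
        values = np.atleast_2d(np.asarray(expr, dtype=float))
    q1, q3 = np.percentile(values, [25, 75], axis=1, method="linear")
    return q3 - q1


def bidimensional_screen(
    p_adj: np.ndarray,
    iqr: np.ndarray,
    p_threshold: float,
    iqr_threshold: float,
    gene_ids: np.ndarray | None = None,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Conjunction screen: keep gene g iff p_adj[g] <= p_threshold and
    iqr[g] >= iqr_threshold.

    p_threshold = 1 disables the supervised screen, iqr_threshold = 0 the
    unsupervised one; (1, 0) is the no-screening condition. Thresholds off
    the configured grids are allowed but warned about, since grid cells are
    meant to be comparable across runs.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    iqr = np.asarray(iqr, dtype=float)
    if p_adj.shape != iqr.shape:
        raise ValidationError("p_adj and iqr must align")
    cfg = config or ScreenConfig()
    if p_threshold not in cfg.p_grid or iqr_threshold not in cfg.iqr_grid:
        warnings.warn(
            f"thresholds ({p_threshold}, {iqr_threshold}) are off the configured grids",
            stacklevel=2,
        )
    mask = (p_adj <= p_threshold) & (iqr >= iqr_threshold)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(len(p_adj))], dtype=object)
    return ScreenResult(np.asarray(gene_ids, dtype=object), p_adj, iqr, mask,
                        (p_threshold, iqr_threshold))


def topk_screen(
    p_raw: np.ndarray,
    k: int,
    abs_beta: np.ndarray | None = None,
    gene_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Keep exactly min(k, n_genes) genes with the smallest raw p-values.

    Deterministic tie-break at the boundary: larger |beta| first, then
    lexicographic gene id.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    m = len(p_raw)
    abs_beta = np.zeros(m) if abs_beta is None else np.abs(np.asarray(abs_beta, float))
    if gene_ids is None:
        gene_ids = np.array([f"g{i:06d}" for i in range(m)], dtype=object)
    # lexsort: last key is primary
    order = np.lexsort((np.asarray(gene_ids, dtype=object), -abs_beta, p_raw))
    mask = np.zeros(m, dtype=bool)
    mask[order[: min(k, m)]] = True
    return mask


def correlation_prefilter(
    values: np.ndarray, p_raw: np.ndarray, r_threshold: float = 0.5
) -> np.ndarray:
    """Greedy de-correlation: visit genes by ascending p-value and accept a
    gene only if its absolute Pearson correlation with every already
    accepted gene is <= r_threshold. Keeps the most survival-associated
    member of each correlated group."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    p_raw = np.asarray(p_raw, dtype=float)
    g, n = values.shape
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    unit = centered / norms[:, None]
    order = np.argsort(p_raw, kind="stable")
    accepted: list[int] = []
    mask = np.zeros(g, dtype=bool)
    acc_rows = np.empty((0, n))
    for j in order:
        if acc_rows.shape[0]:
            corr = acc_rows @ unit[j]
            if np.any(np.abs(corr) > r_threshold):
                continue
        accepted.append(j)
        acc_rows = np.vstack([acc_rows, unit[j]])
        mask[j] = True
    return mask


def sis_default_d(n: int) -> int:
    """Recommended screening size d = floor(n / log(n))."""
    return int(np.floor(n / np.log(n)))


def sis_rank(expr, data: SurvivalData) -> np.ndarray:
    """Sure independence screening ranking: gene indices sorted by
    single-variable Cox |beta| descending (diverged fits rank by the capped
    coefficient). Returns the permutation; take the first d for a screen."""
    values = expr.values if hasattr(expr, "values") else np.atleast_2d(np.asarray(expr, float))
    beta, _, _, _ = single_gene_fits(values, data)
    return np.argsort(-np.abs(beta), kind="stable")


@dataclass
class IsisResult:
    mask: np.ndarray
    converged: bool
    d_used: int
    n_iterations: int


def isis_screen(
    expr,
    data: SurvivalData,
    d: int | None = None,
    max_iterations: int = 5,
    seed: int = 0,
    n_lambdas: int = 50,
) -> IsisResult:
    """Iterative sure independence screening with a lasso refinement step.

    Starting from the top-d SIS set, each iteration fits a lasso-penalized
    Cox model on the current candidate set, then lets every excluded gene
    compete again through its conditional contribution — a single-variable
    Cox fit with the current prognostic index as a fixed offset — and
    re-selects up to d genes. Stops when the candidate set repeats or after
    ``max_iterations``. On non-convergence the procedure is retried with
    d/2 and then d/4 (the fallback ladder); if that still fails the last
    iterate is returned flagged.
    """
    values = expr.values if hasattr(expr, "values") else np.atleast_2d(np.asarray(expr, float))
    n = values.shape[1]
    if d is None:
        d = sis_default_d(n)
    if d < 1:
        raise ValidationError("d must be >= 1")
    ladder = [d, max(d // 2, 1), max(d // 4, 1)]
    last: IsisResult | None = None
    for d_try in ladder:
        res = _isis_once(values, data, d_try, max_iterations, seed, n_lambdas)
        if res.converged:
            return res
        last = res
    warnings.warn("ISIS did not converge after the fallback ladder", stacklevel=2)
    return last


def _isis_once(values, data, d, max_iterations, seed, n_lambdas) -> IsisResult:
    g = values.shape[0]
    beta, _, _, _ = single_gene_fits(values, data)
    current = set(np.argsort(-np.abs(beta), kind="stable")[:d].tolist())
    lasso = PenaltySpec("lasso")
    it = 0
    converged = False
    for it in range(1, max_iterations + 1):
        idx = np.array(sorted(current))
        X = values[idx].T
        fit = fit_penalized_cv(X, data, lasso, K_inner=3, seed=seed + it,
                               n_lambdas=n_lambdas)
        nz = idx[fit.params != 0]
        selected = set(nz.tolist()) if nz.size else set(list(current)[:1])
        pi = X @ fit.params
        excluded = np.array(sorted(set(range(g)) - selected))
        room = d - len(selected)
        if room > 0 and excluded.size:
            b_cond, _, _, _ = single_gene_fits(values[excluded], data, offset=pi)
            add = excluded[np.argsort(-np.abs(b_cond), kind="stable")[:room]]
            new = selected | set(add.tolist())
        else:
            new = selected
        if new == current:
            converged = True
            break
        current = new
    mask = np.zeros(g, dtype=bool)
    mask[sorted(current)] = True
    return IsisResult(mask, converged, d, it)
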