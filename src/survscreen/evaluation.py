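"""Repeated and nested cross-validated evaluation of the screening +
penalized-Cox pipeline.

The evaluation contract: for every train/test split, *all* data-dependent
choices — the expressed-gene filter, standardization parameters, screening
statistics (single-gene p-values, VST IQRs), and the penalty strength — are
computed on the training fold only, then frozen and applied to the test
fold. 10 repetitions of event-stratified 5-fold CV yield 50 C-index and 50
IBS values per pipeline configuration. The bi-dimensional threshold grid
search shares fold partitions across cells so conditions can be compared
with paired Wilcoxon signed-rank tests; the nested phase re-runs the chosen
thresholds on fresh partitions (a new seed stream) to avoid optimism from
tuning and testing on the same splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .containers import SurvivalData, SurvivalDataset, ValidationError
from .coxph import CoxPH, CoxPHResults, breslow_baseline, single_gene_pvalues
from .metrics import concordance_index, integrated_brier, prognostic_index
from .penalized import PenaltySpec, fit_penalized_cv
from .preprocess import cpm_normalize, filter_expressed, standardize, vst_transform
from .screening import ScreenConfig, iqr_scores

__all__ = [
    "CVConfig",
    "CVResult",
    "ThresholdGrid",
    "repeated_kfold",
    "grid_search_thresholds",
    "nested_evaluation",
    "nested_comparison",
    "integrate_clinical",
    "encode_clinical",
    "compare_conditions",
    "bh_family",
    "inclusion_rule",
]


@dataclass
class CVConfig:
    K: int = 5
    repetitions: int = 10
    seed: int = 0
    penalty: PenaltySpec = field(default_factory=lambda: PenaltySpec("lasso"))
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    thresholds: tuple[float, float] = (1.0, 0.0)   # (p, IQR); (1, 0) = no screening
    K_inner: int = 5
    n_lambdas: int = 100
    metric_for_optimum: str = "c_index"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValidationError("K must be >= 2")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.metric_for_optimum not in ("c_index", "ibs"):
            raise ValidationError("metric_for_optimum must be c_index or ibs")

    def provenance(self) -> dict:
        return {
            "K": self.K, "repetitions": self.repetitions, "seed": self.seed,
            "penalty": self.penalty.kind, "alpha": self.penalty.alpha,
            "thresholds": tuple(self.thresholds), "K_inner": self.K_inner,
            "n_lambdas": self.n_lambdas,
        }


@dataclass
class CVResult:
    """K x repetitions per-split metric samples for one configuration."""

    samples: pd.DataFrame          # rep, fold, c_index, ibs, n_comparable, ...
    config: dict = field(default_factory=dict)

    def metric(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy()

    def median(self, name: str) -> float:
        return float(np.nanmedian(self.metric(name)))

    def split_ids(self) -> list[tuple[int, int]]:
        return list(zip(self.samples["rep"], self.samples["fold"]))


# ---------------------------------------------------------------------------
# fold partitions
# ---------------------------------------------------------------------------

def _partitions(event: np.ndarray, K: int, repetitions: int, seed: int,
                min_train_events: int = 2):
    """Event-stratified fold partitions for every repetition; re-drawn when a
    fold lacks test events or the training side is event-poor."""
    out = []
    for rep in range(repetitions):
        ok = None
        for attempt in range(10):
            rs = (seed * 1_000_003 + rep * 101 + attempt * 7_919) % (2**31 - 1)
            skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=rs)
            folds = list(skf.split(np.zeros(len(event)), event))
            if all(
                event[tr].sum() >= min_train_events and event[te].sum() >= 1
                for tr, te in folds
            ):
                ok = folds
                break
        if ok is None:
            raise ValidationError("could not stratify folds with enough events")
        out.append((rep, ok))
    return out


# ---------------------------------------------------------------------------
# per-split pipeline
# ---------------------------------------------------------------------------

@dataclass
class _SplitData:
    """Training-fold artifacts plus frozen test-fold design, ready for any
    threshold cell. Everything data-dependent is computed from the training
    fold only."""

    rep: int
    fold: int
    gene_ids: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    iqr: np.ndarray
    X_train: np.ndarray            # patients x filtered genes, standardized
    X_test: np.ndarray
    surv_train: SurvivalData
    surv_test: SurvivalData
    inner_seed: int


def _prepare_split(dataset: SurvivalDataset, train_idx, test_idx, rep: int,
                   fold: int, config: CVConfig) -> _SplitData:
    train = dataset.subset_patients(train_idx)
    test = dataset.subset_patients(test_idx)

    keep = filter_expressed(train.counts)
    counts_tr = train.counts.subset_genes(keep)
    counts_te = test.counts.subset_genes(keep)

    log_tr = cpm_normalize(counts_tr, log2=True)
    log_te = cpm_normalize(counts_te, log2=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = standardize(log_tr, log_te, mode="train_params")

    iqr = iqr_scores(vst_transform(counts_tr))
    scan = single_gene_pvalues(std.train, train.survival)

    inner_seed = (config.seed * 92_821 + rep * 53 + fold * 7 + 13) % (2**31 - 1)
    return _SplitData(
        rep=rep, fold=fold, gene_ids=counts_tr.gene_ids,
        p_raw=scan["p"].to_numpy(), p_adj=scan["p_adj"].to_numpy(), iqr=iqr,
        X_train=std.train.values.T, X_test=std.test.values.T,
        surv_train=train.survival, surv_test=test.survival,
        inner_seed=inner_seed,
    )


def _eval_cell(sd: _SplitData, thresholds: tuple[float, float], config: CVConfig) -> dict:
    p_thr, iqr_thr = thresholds
    mask = (sd.p_adj <= p_thr) & (sd.iqr >= iqr_thr)
    X_tr = sd.X_train[:, mask]
    X_te = sd.X_test[:, mask]
    fit = fit_penalized_cv(
        X_tr, sd.surv_train, config.penalty, K_inner=config.K_inner,
        seed=sd.inner_seed, n_lambdas=config.n_lambdas,
    )
    pi_te = prognostic_index(fit, X_te) if mask.any() else np.zeros(X_te.shape[0])
    cres = concordance_index(pi_te, sd.surv_test)
    if mask.any():
        baseline = breslow_baseline(fit, X_tr, sd.surv_train)
        risk = np.exp(np.clip(pi_te, -500, 500))
        ibs = integrated_brier(
            lambda t: np.exp(-baseline.at(np.array([t]))[0] * risk), sd.surv_test
        )
    else:
        ibs = integrated_brier(
            lambda t: np.full(len(sd.surv_test), 0.5), sd.surv_test
        )
    return {
        "rep": sd.rep, "fold": sd.fold,
        "c_index": cres.c_index, "ibs": ibs,
        "n_comparable": cres.n_comparable,
        "n_genes_screened": int(mask.sum()),
        "n_genes_selected": int(np.count_nonzero(fit.params)) if mask.any() else 0,
        "p_threshold": p_thr, "iqr_threshold": iqr_thr,
    }


def _prepare_all_splits(dataset: SurvivalDataset, config: CVConfig,
                        seed: int | None = None) -> list[_SplitData]:
    seed = config.seed if seed is None else seed
    parts = _partitions(dataset.survival.event, config.K, config.repetitions,
                        seed, min_train_events=max(2, config.K_inner))
    splits = []
    for rep, folds in parts:
        for fold, (tr, te) in enumerate(folds):
            splits.append(_prepare_split(dataset, tr, te, rep, fold, config))
    return splits


def repeated_kfold(dataset: SurvivalDataset, config: CVConfig,
                   _splits: list[_SplitData] | None = None) -> CVResult:
    """10 repetitions (default) of event-stratified K-fold CV of the full
    pipeline at the config's fixed screening thresholds; returns
    K x repetitions metric samples."""
    splits = _splits if _splits is not None else _prepare_all_splits(dataset, config)
    rows = [_eval_cell(sd, config.thresholds, config) for sd in splits]
    return CVResult(pd.DataFrame(rows), config.provenance())


@dataclass
class ThresholdGrid:
    """Median metrics per (p, IQR) threshold cell plus the optimal cells."""

    p_grid: tuple
    iqr_grid: tuple
    median_c: np.ndarray           # len(iqr_grid) x len(p_grid)
    median_ibs: np.ndarray
    median_kept: np.ndarray
    optimal: dict                  # metric -> (p_threshold, iqr_threshold)
    cells: dict                    # (p, iqr) -> CVResult

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.iqr_grid):
            for j, p in enumerate(self.p_grid):
                rows.append({
                    "p_threshold": p, "iqr_threshold": q,
                    "median_c_index": self.median_c[i, j],
                    "median_ibs": self.median_ibs[i, j],
                    "median_n_genes": self.median_kept[i, j],
                })
        return pd.DataFrame(rows)


def grid_search_thresholds(dataset: SurvivalDataset, config: CVConfig) -> ThresholdGrid:
    """Evaluate every (p, IQR) cell of the screening grids with shared fold
    partitions (paired design). The optimal cell maximizes the median
    C-index (resp. minimizes the median IBS); ties break toward fewer kept
    genes, then the stricter p-threshold."""
    splits = _prepare_all_splits(dataset, config)
    p_grid, iqr_grid = config.screen.p_grid, config.screen.iqr_grid
    nI, nP = len(iqr_grid), len(p_grid)
    med_c = np.zeros((nI, nP))
    med_ibs = np.zeros((nI, nP))
    med_kept = np.zeros((nI, nP))
    cells = {}
    for i, q in enumerate(iqr_grid):
        for j, p in enumerate(p_grid):
            rows = [_eval_cell(sd, (p, q), config) for sd in splits]
            res = CVResult(pd.DataFrame(rows), {**config.provenance(),
                                                "thresholds": (p, q)})
            cells[(p, q)] = res
            med_c[i, j] = res.median("c_index")
            med_ibs[i, j] = res.median("ibs")
            med_kept[i, j] = res.median("n_genes_screened")

    def _pick(metric_grid, maximize):
        flat = []
        for i, q in enumerate(iqr_grid):
            for j, p in enumerate(p_grid):
                key = -metric_grid[i, j] if maximize else metric_grid[i, j]
                flat.append((key, med_kept[i, j], p, q))
        flat.sort(key=lambda r: (r[0], r[1], r[2]))
        return (flat[0][2], flat[0][3])

    optimal = {
        "c_index": _pick(med_c, maximize=True),
        "ibs": _pick(med_ibs, maximize=False),
    }
    return ThresholdGrid(p_grid, iqr_grid, med_c, med_ibs, med_kept, optimal, cells)


NESTED_SEED_OFFSET = 500_009  # fresh resampling stream for the nested phase


def nested_evaluation(dataset: SurvivalDataset, thresholds: tuple[float, float],
                      config: CVConfig) -> CVResult:
    """Re-run the pipeline with the given (already chosen) thresholds on
    fresh fold partitions, so the reported performance is not biased by the
    grid search having seen the same splits."""
    cfg = CVConfig(**{**config.__dict__, "thresholds": tuple(thresholds),
                      "seed": config.seed + NESTED_SEED_OFFSET})
    splits = _prepare_all_splits(dataset, cfg)
    return repeated_kfold(dataset, cfg, _splits=splits)


def nested_comparison(dataset: SurvivalDataset, thresholds: tuple[float, float],
                      config: CVConfig) -> dict[str, CVResult]:
    """Nested evaluation of the chosen thresholds and of the no-screening
    condition on the same fresh partitions (paired)."""
    base = CVConfig(**{**config.__dict__, "seed": config.seed + NESTED_SEED_OFFSET})
    splits = _prepare_all_splits(dataset, base)
    out = {}
    for name, thr in (("screened", tuple(thresholds)), ("no_screening", (1.0, 0.0))):
        cfg = CVConfig(**{**base.__dict__, "thresholds": thr})
        out[name] = repeated_kfold(dataset, cfg, _splits=splits)
    return out


# ---------------------------------------------------------------------------
# clinical integration
# ---------------------------------------------------------------------------

_GENDER_MAP = {"male": 0.0, "m": 0.0, "female": 1.0, "f": 1.0}


def encode_clinical(clinical: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Encode clinical covariates: age numeric, gender binary, grade/T/N/M
    ordinal integers (digits extracted from codes like 'T2'). Columns with
    missing values are dropped with a warning."""
    cols, names = [], []
    for col in clinical.columns:
        s = clinical[col]
        if s.isna().any():
            warnings.warn(f"clinical column {col!r} has missing values; dropped",
                          stacklevel=2)
            continue
        if col.lower() == "gender":
            enc = s.astype(str).str.lower().map(_GENDER_MAP)
            if enc.isna().any():
                warnings.warn(f"unparseable gender values; column dropped", stacklevel=2)
                continue
        elif s.dtype.kind in "ifu":
            enc = s.astype(float)
        else:
            enc = pd.to_numeric(
                s.astype(str).str.extract(r"(\d+)", expand=False), errors="coerce"
            )
            if enc.isna().any():
                warnings.warn(f"unparseable values in clinical column {col!r}; dropped",
                              stacklevel=2)
                continue
        cols.append(enc.to_numpy(float))
        names.append(col)
    if not cols:
        return np.zeros((len(clinical), 0)), []
    return np.column_stack(cols), names


def integrate_clinical(pi_mrna: np.ndarray, clinical: pd.DataFrame,
                       data: SurvivalData) -> tuple[CoxPHResults, np.ndarray]:
    """Combine the mRNA prognostic index with clinical covariates through an
    unpenalized Cox model: PI = beta * PI_mRNA + sum_k beta_k * Clin_k.

    Returns the fitted model and the combined prognostic index on the same
    patients. Apply to a test fold by encoding its clinical table and using
    ``fit.predict_pi``.
    """
    pi_mrna = np.asarray(pi_mrna, dtype=float)
    if len(pi_mrna) != len(data):
        raise ValidationError("PI length must match survival data")
    C, names = encode_clinical(clinical)
    X = np.column_stack([pi_mrna, C])
    fit = CoxPH(X, data, var_names=["pi_mrna"] + names).fit()
    return fit, fit.predict_pi(X)


# ---------------------------------------------------------------------------
# distribution comparisons
# ---------------------------------------------------------------------------

def compare_conditions(a: CVResult, b: CVResult, metric: str = "c_index",
                       alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value comparing paired per-split
    metric values of two conditions (exact null for small n after zero
    removal; normal approximation with continuity correction otherwise).
    All-zero differences give p = 1."""
    if a.split_ids() != b.split_ids():
        raise ValidationError("conditions are not paired: split identifiers differ")
    x = a.metric(metric)
    y = b.metric(metric)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    if np.all(d == 0) or len(d) == 0:
        return 1.0
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative=alternative, method="auto")
    return float(res.pvalue)


def bh_family(pvalues) -> np.ndarray:
    """Benjamini-Hochberg correction across a family of condition
    comparisons."""
    from .coxph import bh_adjust

    return bh_adjust(np.asarray(pvalues, dtype=float))


def inclusion_rule(result: CVResult, reference: float = 0.6,
                   level: float = 0.01) -> bool:
    """Dataset-inclusion rule: the median C-index must be significantly
    above the reference by a one-sample one-sided Wilcoxon signed-rank test."""
    c = result.metric("c_index")
    c = c[np.isfinite(c)]
    if len(c) < 10:
        raise ValidationError("inclusion rule needs at least 10 metric samples")
    d = c - reference
    if np.all(d == 0):
        return False
    p = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="greater", method="auto").pvalue
    return bool(p < level)
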