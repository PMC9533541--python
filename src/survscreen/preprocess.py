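"""Expression normalization, gene filtering, VST, and standardization.

The pipeline convention follows standard bulk RNA-seq practice for survival
modelling: library-size (CPM) normalization with a log2(CPM + 1) transform,
an expressed-gene filter (CPM above a cutoff in a minimum fraction of
patients), a variance-stabilizing transform for the unsupervised screening
statistic, and per-gene standardization with training-set parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "cpm_normalize",
    "filter_expressed",
    "vst_transform",
    "fit_dispersion_trend",
    "standardize",
    "StandardizeResult",
]


def cpm_normalize(m: CountMatrix, log2: bool = True) -> ExpressionMatrix:
    """Counts-per-million normalization, optionally log2(CPM + 1).

    Each sample's counts are divided by its library size and scaled to one
    million, so CPM columns sum to 1e6. The pseudo-count of 1 in the log
    transform maps zero counts to exactly 0 and keeps the map monotone.
    """
    lib = m.counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        bad = m.sample_ids[lib <= 0]
        raise ValidationError(f"zero library size for samples: {list(bad)[:5]}")
    cpm = m.counts / lib * 1e6
    if log2:
        return ExpressionMatrix(m.gene_ids, m.sample_ids, np.log2(cpm + 1.0), "log2cpm")
    return ExpressionMatrix(m.gene_ids, m.sample_ids, cpm, "cpm")


def filter_expressed(
    m: CountMatrix, cpm_threshold: float = 1.0, patient_fraction: float = 0.01
) -> np.ndarray:
    """Mask of expressed genes: CPM strictly above ``cpm_threshold`` in at
    least ``ceil(patient_fraction * n_patients)`` patients."""
    cpm = cpm_normalize(m, log2=False).values
    need = int(np.ceil(patient_fraction * m.n_samples))
    return (cpm > cpm_threshold).sum(axis=1) >= need


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (reference = geometric mean over samples).

    Only genes with all-positive counts contribute; if none exist, fall back
    to library-size factors normalized to geometric mean 1.
    """
    pos = np.all(counts > 0, axis=1)
    if pos.sum() >= 1:
        logc = np.log(counts[pos].astype(float))
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        lib = counts.sum(axis=0).astype(float)
        lib = np.maximum(lib, 1.0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    return sf


def fit_dispersion_trend(counts: np.ndarray, sf: np.ndarray) -> tuple[float, float]:
    """Fit the two-parameter dispersion trend alpha(mu) = a0 + a1 / mu.

    Per-gene dispersions come from the method of moments on size-factor
    normalized counts: alpha_g = (s^2 - mu) / mu^2. The trend is an ordinary
    least-squares fit of alpha_g on 1/mu_g over informative genes, with both
    coefficients clipped to be non-negative (a0 floored slightly above zero
    so the closed-form transform stays defined).
    """
    q = counts / sf
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    keep = mu > 0.5
    mu_k, var_k = mu[keep], var[keep]
    disp = (var_k - mu_k) / mu_k**2
    ok = np.isfinite(disp)
    mu_k, disp = mu_k[ok], disp[ok]
    if len(disp) < 2:
        return 1e-8, 0.0
    A = np.column_stack([np.ones_like(mu_k), 1.0 / mu_k])
    coef, *_ = np.linalg.lstsq(A, disp, rcond=None)
    a0 = float(max(coef[0], 1e-8))
    a1 = float(max(coef[1], 0.0))
    return a0, a1


def vst_transform(m: CountMatrix) -> ExpressionMatrix:
    """Variance-stabilizing transform for count data.

    Normalizes by median-of-ratios size factors, fits the dispersion trend
    alpha(mu) = a0 + a1/mu (so Var = (1+a1)*mu + a0*mu^2), then applies the
    closed-form transform

        f(q) = (2 / sqrt(a0)) * asinh(sqrt(a0 * q / (1 + a1)))

    whose derivative is 1/sqrt(Var(q)), to normalized counts. For a0 -> 0
    (and a1 = 0) this approaches the Poisson square-root limit 2*sqrt(q).
    The transform removes the median-IQR trend that raw or log counts
    exhibit, so IQR screening treats low and high expressors on an equal
    footing.
    """
    if m.n_samples < 2:
        raise ValidationError("VST requires at least 2 samples")
    sf = _size_factors(m.counts)
    a0, a1 = fit_dispersion_trend(m.counts, sf)
    q = m.counts / sf
    vals = (2.0 / np.sqrt(a0)) * np.arcsinh(np.sqrt(a0 * q / (1.0 + a1)))
    return ExpressionMatrix(m.gene_ids, m.sample_ids, vals, "vst")


@dataclass
class StandardizeResult:
    train: ExpressionMatrix
    test: ExpressionMatrix
    mean: np.ndarray
    sd: np.ndarray
    zero_sd_genes: np.ndarray  # gene ids with zero scaling SD (flagged, scaled by 1)


def standardize(
    train: ExpressionMatrix, test: ExpressionMatrix, mode: str = "train_params"
) -> StandardizeResult:
    """Per-gene centering and scaling of train/test expression.

    mode="train_params": both matrices use the training mean/SD (the
    cross-validation convention). mode="test_params": the test matrix is
    scaled by its own statistics — the external-cohort convention used when
    train and test come from different experiments whose location/scale are
    not comparable. Zero-SD genes are scaled by 1 and flagged rather than
    erroring, since screening can remove them downstream.
    """
    if list(train.gene_ids) != list(test.gene_ids):
        raise ValidationError("train and test must share gene_ids in order")
    if mode not in ("train_params", "test_params"):
        raise ValidationError(f"unknown standardization mode {mode!r}")

    mean = train.values.mean(axis=1)
    sd = train.values.std(axis=1, ddof=0)
    zero = sd == 0
    sd_safe = np.where(zero, 1.0, sd)
    train_std = (train.values - mean[:, None]) / sd_safe[:, None]

    if mode == "train_params":
        test_std = (test.values - mean[:, None]) / sd_safe[:, None]
    else:
        t_mean = test.values.mean(axis=1)
        t_sd = test.values.std(axis=1, ddof=0)
        t_sd = np.where(t_sd == 0, 1.0, t_sd)
        test_std = (test.values - t_mean[:, None]) / t_sd[:, None]

    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) with zero training SD scaled by 1",
            stacklevel=2,
        )
    return StandardizeResult(
        ExpressionMatrix(train.gene_ids, train.sample_ids, train_std, "standardized"),
        ExpressionMatrix(test.gene_ids, test.sample_ids, test_std, "standardized"),
        mean,
        sd,
        train.gene_ids[zero],
    )
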