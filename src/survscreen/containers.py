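"""Core data containers: count/expression matrices and survival tables.

Matrices are stored genes x patients, mirroring the layout of bulk RNA-seq
count tables (first column gene identifiers, header row sample identifiers).
All containers are thin wrappers around numpy arrays with identifier
bookkeeping and validation; they read and write plain TSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SurvivalData",
    "SurvivalDataset",
    "ValidationError",
    "read_counts_tsv",
    "read_survival_tsv",
    "read_clinical_tsv",
]


class ValidationError(ValueError):
    """Raised when an input table or parameter violates its contract."""


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what} identifiers: {dup}")
    return ids


@dataclass
class CountMatrix:
    """Raw integer expression counts, genes x patients."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        return CountMatrix(
            self.gene_ids[mask_or_idx], self.sample_ids, self.counts[mask_or_idx]
        )

    def subset_samples(self, idx) -> "CountMatrix":
        return CountMatrix(self.gene_ids, self.sample_ids[idx], self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        _write_matrix_tsv(self.to_frame(), path, "gene_id", header_lines)


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x patients, with transform provenance.

    ``transform_tag`` is one of {"cpm", "log2cpm", "vst", "standardized"}.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    transform_tag: str = "cpm"

    _TAGS = ("cpm", "log2cpm", "vst", "standardized")

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape inconsistent with identifiers")
        if self.transform_tag not in self._TAGS:
            raise ValidationError(f"unknown transform_tag {self.transform_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.gene_ids[mask_or_idx],
            self.sample_ids,
            self.values[mask_or_idx],
            self.transform_tag,
        )

    def subset_samples(self, idx) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.gene_ids, self.sample_ids[idx], self.values[:, idx], self.transform_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SurvivalData:
    """Per-patient follow-up time and event indicator (1 = event observed)."""

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != self.sample_ids.shape or self.event.shape != self.time.shape:
            raise ValidationError("survival columns must align with sample identifiers")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValidationError("survival times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event indicator must be 0 or 1")
        self.event = self.event.astype(np.int64)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.sample_ids[idx], self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        _write_table_tsv(self.to_frame(), path, header_lines)


@dataclass
class SurvivalDataset:
    """A matched expression + survival (+ optional clinical) cohort."""

    counts: CountMatrix
    survival: SurvivalData
    clinical: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cs = list(self.counts.sample_ids)
        ss = list(self.survival.sample_ids)
        if cs != ss:
            missing = sorted(set(cs).symmetric_difference(ss))
            raise ValidationError(
                "sample identifiers differ between counts and survival tables; "
                f"offenders: {missing[:10]}"
            )
        if self.clinical is not None:
            if list(self.clinical.index) != cs:
                raise ValidationError("clinical table index must match sample order")

    @property
    def n_patients(self) -> int:
        return self.counts.n_samples

    def subset_patients(self, idx) -> "SurvivalDataset":
        clin = self.clinical.iloc[idx] if self.clinical is not None else None
        return SurvivalDataset(
            self.counts.subset_samples(idx), self.survival.subset(idx), clin
        )


# ---------------------------------------------------------------------------
# TSV I/O (plain text; '#' lines at the top carry provenance and are skipped)
# ---------------------------------------------------------------------------

def _write_matrix_tsv(df: pd.DataFrame, path, index_name: str, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.index.name = index_name
        df.to_csv(fh, sep="\t")


def _write_table_tsv(df: pd.DataFrame, path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> CountMatrix:
    """Read a genes x samples count matrix (first column gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise ValidationError(f"malformed count TSV {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"count TSV {path} contains no data rows")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValidationError(
            f"non-numeric counts in {path}, columns: {list(bad)[:5]}"
        )
    return CountMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), vals)


def read_survival_tsv(path) -> SurvivalData:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed survival TSV {path}: {exc}") from exc
    needed = {"sample_id", "time", "event"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"survival TSV {path} must have columns {sorted(needed)}, "
            f"found {list(df.columns)}"
        )
    return SurvivalData(
        df["sample_id"].to_numpy(object),
        df["time"].to_numpy(float),
        df["event"].to_numpy(),
    )


def read_clinical_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed clinical TSV {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ValidationError(f"clinical TSV {path} must have a sample_id column")
    return df.set_index("sample_id")


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for provenance headers."""
    return hashlib.sha256(repr(sorted(str(obj).split())).encode()).hexdigest()[:12]
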