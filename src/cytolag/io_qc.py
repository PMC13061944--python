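"""Count-matrix IO, per-cell QC, cell filtering and normalization.

Count matrices are features x cells, integer, one per modality (``rna`` or
``adt``).  On disk they are MatrixMarket triplets (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped) or dense CSV for
small examples.  Cell metadata and feature annotation travel as pandas
DataFrames indexed by cell / feature id.

QC follows the standard single-cell conventions: number of detected
features, total counts and mitochondrial percentage per cell, with cells
excluded when they fall outside the detected-feature window or exceed the
mitochondrial cutoff.  RNA is log-normalized (counts per 10,000, ln(1+x));
ADT is CLR-normalized per feature across the cells of each sample.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

Modality = Literal["rna", "adt"]

CONDITIONS = ("stimulated", "unstimulated")


class InputError(ValueError):
    """Missing or malformed input files."""


class ValidationError(ValueError):
    """Data violating a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer feature x cell count matrix for one modality.

    Parameters
    ----------
    values
        Non-negative integer array of shape ``(n_features, n_cells)``.
    feature_ids, cell_ids
        Unique string identifiers for rows / columns.
    modality
        ``"rna"`` or ``"adt"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    modality: Modality

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.modality not in ("rna", "adt"):
            raise ValidationError(f"modality must be 'rna' or 'adt', got {self.modality!r}")
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.cell_ids, "cell")
        _check_counts_integral(self.values)
        self.values = self.values.astype(np.int64, copy=False)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        """Return a new matrix restricted to a boolean mask or list of cell ids."""
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return CountMatrix(
            self.values[:, idx],
            self.feature_ids,
            [self.cell_ids[i] for i in idx],
            self.modality,
        )


@dataclass
class NormMatrix:
    """Normalized real-valued feature x cell matrix.

    ``method`` records how values were produced: ``lognorm_cp10k`` for RNA
    (ln(1 + 1e4 * count / cell_total)) or ``clr_per_feature`` for ADT
    (per-feature centered log-ratio across the cells of each sample).
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    method: Literal["lognorm_cp10k", "clr_per_feature"]
    sample_partition: dict[str, str] | None = None
    # per-(feature, sample) constants removed by CLR centering; adding them
    # back recovers mean log1p abundance, the meaningful gene-level scale
    feature_offsets: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValidationError("normalized matrix shape does not match ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)

    def subset_cells(self, mask_or_ids) -> "NormMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        part = None
        if self.sample_partition is not None:
            part = {self.cell_ids[i]: self.sample_partition[self.cell_ids[i]] for i in idx}
        return NormMatrix(
            self.values[:, idx],
            self.feature_ids,
            [self.cell_ids[i] for i in idx],
            self.method,
            part,
            self.feature_offsets,
        )


@dataclass
class QCMetrics:
    """Per-cell QC metrics: detected features, totals, mito percentage."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("n_features_detected", "total_counts", "pct_mito", "degenerate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"QC table missing columns: {missing}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def _check_unique(ids: list[str], axis: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {axis} ids: {dups[:5]}")


def _check_counts_integral(values: np.ndarray) -> None:
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("counts must be numeric")
    bad = np.argwhere((values < 0) | (values != np.floor(values)))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"counts must be non-negative integers; offending entry at "
            f"(feature {r}, cell {c}) = {values[r, c]!r}"
        )


def _cell_indexer(cell_ids: list[str], mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != (len(cell_ids),):
            raise ValidationError("boolean mask length does not match cell count")
        return np.flatnonzero(arr)
    pos = {c: i for i, c in enumerate(cell_ids)}
    try:
        return np.array([pos[str(c)] for c in mask_or_ids], dtype=int)
    except KeyError as e:  # pragma: no cover - message path
        raise ValidationError(f"unknown cell id {e.args[0]!r}") from None


# ---------------------------------------------------------------------------
# metadata validation
# ---------------------------------------------------------------------------


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell metadata table (index = cell_id).

    Required columns: ``sample_id``, ``condition`` (stimulated/unstimulated),
    ``cell_type``.  Optional: ``true_pseudotime`` in [0, 1] (synthetic data).
    """
    meta = meta.copy()
    if "cell_id" in meta.columns and meta.index.name != "cell_id":
        meta = meta.set_index("cell_id")
    for col in ("sample_id", "condition", "cell_type"):
        if col not in meta.columns:
            raise ValidationError(f"cell metadata missing column {col!r}")
    if meta.index.has_duplicates:
        raise ValidationError("cell metadata has duplicated cell ids")
    bad = set(meta["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition values: {sorted(bad)}")
    if "true_pseudotime" in meta.columns:
        t = meta["true_pseudotime"].dropna()
        if len(t) and ((t < 0).any() or (t > 1).any()):
            raise ValidationError("true_pseudotime must lie in [0, 1]")
    return meta


def validate_feature_annotation(ann: pd.DataFrame, adt_ids: list[str] | None = None) -> pd.DataFrame:
    """Validate a feature annotation table (index = feature_id).

    Required columns: ``is_mito``, ``category``, ``is_cytokine``; optional
    ``paired_adt_id`` linking an RNA feature to its ADT counterpart.
    """
    ann = ann.copy()
    if "feature_id" in ann.columns and ann.index.name != "feature_id":
        ann = ann.set_index("feature_id")
    for col in ("is_mito", "category", "is_cytokine"):
        if col not in ann.columns:
            raise ValidationError(f"feature annotation missing column {col!r}")
    if ann.index.has_duplicates:
        raise ValidationError("feature annotation has duplicated feature ids")
    ann["is_mito"] = ann["is_mito"].astype(bool)
    ann["is_cytokine"] = ann["is_cytokine"].astype(bool)
    inconsistent = ann.index[ann["is_cytokine"] & (ann["category"] != "cytokine")]
    if len(inconsistent):
        raise ValidationError(
            f"is_cytokine implies category == 'cytokine'; violated by {list(inconsistent[:5])}"
        )
    if adt_ids is not None and "paired_adt_id" in ann.columns:
        pairs = ann["paired_adt_id"].dropna()
        unknown = set(pairs) - set(adt_ids)
        if unknown:
            raise ValidationError(f"paired_adt_id refers to unknown ADT features: {sorted(unknown)[:5]}")
    return ann


def flag_mito_features(feature_ids: list[str]) -> np.ndarray:
    """Boolean mask of features whose id starts with 'MT-' (case-insensitive)."""
    return np.array([str(f).upper().startswith("MT-") for f in feature_ids], dtype=bool)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _find_one(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise InputError(f"missing {stem}[.gz] in {directory}")


def _read_id_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str | Path, modality: Modality) -> CountMatrix:
    """Read a count matrix from an MTX-triplet directory or a dense CSV file.

    A directory must contain ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` and
    ``barcodes.tsv[.gz]``; a file is parsed as CSV with feature rows and a
    header of cell ids.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find_one(path, "matrix.mtx")
        features = _read_id_column(_find_one(path, "features.tsv"))
        barcodes = _read_id_column(_find_one(path, "barcodes.tsv"))
        mat = scipy.io.mmread(str(mtx))
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        return CountMatrix(values, features, barcodes, modality)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns), modality)


def write_counts(counts: CountMatrix, path: str | Path) -> Path:
    """Write a CountMatrix as an MTX triplet into a directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sparse, field="integer")
    (path / "features.tsv").write_text("".join(f"{f}\n" for f in counts.feature_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a tab-separated table with header."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(obj: pd.DataFrame | QCMetrics, path: str | Path, index: bool = True) -> Path:
    """Write a DataFrame (or QCMetrics) as a tab-separated file with header."""
    table = obj.table if isinstance(obj, QCMetrics) else obj
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)
    return path


# ---------------------------------------------------------------------------
# QC and filtering
# ---------------------------------------------------------------------------


def compute_qc(counts: CountMatrix, ann: pd.DataFrame) -> QCMetrics:
    """Per-cell QC metrics from an RNA count matrix.

    ``pct_mito`` is 100 * mito counts / total counts per cell, using the
    ``is_mito`` flags in the feature annotation; cells with zero total counts
    get pct_mito = 0 with ``degenerate = True``.
    """
    ann = validate_feature_annotation(ann)
    missing = [f for f in counts.feature_ids if f not in ann.index]
    if missing:
        raise ValidationError(f"features missing from annotation: {missing[:10]}")
    is_mito = ann.loc[counts.feature_ids, "is_mito"].to_numpy(dtype=bool)
    totals = counts.values.sum(axis=0)
    mito_totals = counts.values[is_mito].sum(axis=0) if is_mito.any() else np.zeros_like(totals)
    degenerate = totals == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(degenerate, 0.0, 100.0 * mito_totals / np.where(degenerate, 1, totals))
    table = pd.DataFrame(
        {
            "n_features_detected": (counts.values > 0).sum(axis=0),
            "total_counts": totals,
            "pct_mito": pct,
            "degenerate": degenerate,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )
    return QCMetrics(table)


def filter_cells(
    qc: QCMetrics,
    min_features: int = 200,
    max_features: int = 8000,
    max_pct_mito: float = 20.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Keep-mask for cells passing the QC window.

    A cell is excluded when it has strictly fewer than ``min_features``
    detected features, strictly more than ``max_features``, or strictly more
    than ``max_pct_mito`` percent mitochondrial counts; boundary values are
    kept.  Returns the boolean keep-mask and per-criterion exclusion counts.
    """
    if min_features <= 0 or max_features <= 0 or max_pct_mito <= 0:
        raise ValidationError("filter thresholds must be positive")
    if max_features <= min_features:
        raise ValidationError("max_features must exceed min_features")
    n = qc["n_features_detected"].to_numpy()
    pct = qc["pct_mito"].to_numpy()
    too_few = n < min_features
    too_many = n > max_features
    too_mito = pct > max_pct_mito
    keep = ~(too_few | too_many | too_mito)
    summary = {
        "n_cells": int(len(n)),
        "n_kept": int(keep.sum()),
        "excluded_low_features": int(too_few.sum()),
        "excluded_high_features": int(too_many.sum()),
        "excluded_high_mito": int(too_mito.sum()),
    }
    if summary["n_kept"] == 0:
        logger.warning("filter_cells: no cells pass the QC filters")
    return keep, summary


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def lognorm(counts: CountMatrix) -> NormMatrix:
    """Log-normalize RNA counts: ln(1 + 1e4 * count / cell_total) per cell.

    Cells with zero total counts are dropped with a warning — they should
    already have been removed by QC filtering.
    """
    totals = counts.values.sum(axis=0)
    if (totals == 0).all():
        raise ValidationError("all cells have zero total counts")
    if (totals == 0).any():
        n_zero = int((totals == 0).sum())
        warnings.warn(f"lognorm: dropping {n_zero} zero-total cells", stacklevel=2)
        counts = counts.subset_cells(totals > 0)
        totals = totals[totals > 0]
    values = np.log1p(1e4 * counts.values / totals[None, :])
    return NormMatrix(values, counts.feature_ids, list(counts.cell_ids), "lognorm_cp10k")


def clr_normalize(counts: CountMatrix, sample_of: Mapping[str, str]) -> NormMatrix:
    """CLR-normalize ADT counts per feature across cells, within each sample.

    For feature f and cell c in sample s:
    ``clr(f, c) = ln(1 + count(f, c)) - mean_{c' in s} ln(1 + count(f, c'))``.
    Samples with a single cell yield all-zero values (flagged via warning).
    """
    missing = [c for c in counts.cell_ids if c not in sample_of]
    if missing:
        raise ValidationError(f"cells missing from sample map: {missing[:10]}")
    samples = np.array([sample_of[c] for c in counts.cell_ids])
    log_values = np.log1p(counts.values.astype(float))
    out = np.empty_like(log_values)
    unique_samples = list(np.unique(samples))
    offsets = pd.DataFrame(index=counts.feature_ids, columns=unique_samples, dtype=float)
    for s in unique_samples:
        cols = samples == s
        if cols.sum() == 1:
            warnings.warn(f"clr_normalize: sample {s!r} has a single cell; CLR set to 0", stacklevel=2)
        means = log_values[:, cols].mean(axis=1)
        out[:, cols] = log_values[:, cols] - means[:, None]
        offsets[s] = means
    return NormMatrix(
        out,
        counts.feature_ids,
        list(counts.cell_ids),
        "clr_per_feature",
        {c: sample_of[c] for c in counts.cell_ids},
        offsets,
    )
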