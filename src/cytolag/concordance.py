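"""RNA-protein concordance statistics.

Two levels of analysis:

* per-gene across cells — for each RNA feature with a paired ADT feature,
  Spearman's rho between the normalized RNA and ADT values over a cell
  subset;
* gene-level means — a single rho across genes between per-gene mean
  log-normalized RNA and per-gene mean CLR-normalized ADT, plus separate
  ordinary-least-squares regressions for cytokine and non-cytokine genes,
  whose contrast (lower rho, flatter slope for cytokines) is the headline
  qualitative result this kind of experiment probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import NormMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceRecord",
    "ClassRegressionResult",
    "spearman_rho",
    "per_gene_cell_correlation",
    "gene_level_concordance",
    "category_summary",
    "class_regression",
    "records_to_frame",
]


@dataclass
class ConcordanceRecord:
    """Spearman correlation for one feature (or one gene-level summary)."""

    feature_id: str
    rho: float
    p_value: float
    n: int
    category: str = "other"
    level: str = "per_gene_across_cells"  # or "gene_level_means"
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"|rho| must be <= 1, got {self.rho}")


@dataclass
class ClassRegressionResult:
    """OLS of mean ADT on mean RNA within one gene class, plus Spearman rho."""

    class_label: str  # "cytokine" | "non_cytokine"
    slope: float
    intercept: float
    rho: float
    p_value: float
    n_genes: int
    defined: bool = True


def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided p-value.

    Mid-ranks are used for ties; the p-value comes from the Student-t
    approximation ``t = rho * sqrt((n - 2) / (1 - rho^2))``, with p = 0 at
    rho = +/-1.  With ``exact=True`` (n <= 10) the p-value is computed by
    full enumeration of rank permutations instead.

    Raises
    ------
    ValidationError
        If the vectors differ in length, are shorter than 3, contain
        non-finite values, or either input is constant (undefined rho).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho requires equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("spearman_rho requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("spearman_rho requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman_rho undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-12:  # snap perfect monotone agreement despite fp rounding
        rho = float(np.sign(rho))
    if exact:
        if n > 10:
            raise ValidationError("exact permutation p only supported for n <= 10")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _paired_features(rna_ids: list[str], adt_ids: list[str], ann: pd.DataFrame) -> list[tuple[str, str]]:
    if "paired_adt_id" not in ann.columns:
        raise ValidationError("annotation has no paired_adt_id column")
    adt_set = set(adt_ids)
    pairs = []
    skipped = 0
    for fid in rna_ids:
        if fid not in ann.index:
            skipped += 1
            continue
        partner = ann.loc[fid, "paired_adt_id"]
        if isinstance(partner, str) and partner in adt_set:
            pairs.append((fid, partner))
        else:
            skipped += 1
    if skipped:
        logger.info("per-gene concordance: skipped %d RNA features without ADT pairing", skipped)
    return pairs


def per_gene_cell_correlation(
    rna_norm: NormMatrix,
    adt_norm: NormMatrix,
    ann: pd.DataFrame,
    cell_subset: list[str] | None = None,
) -> list[ConcordanceRecord]:
    """Per-gene Spearman rho across cells for every RNA/ADT paired feature.

    Genes with constant values in either modality produce a flagged
    (``defined=False``) record rather than an imputed rho.
    """
    pairs = _paired_features(rna_norm.feature_ids, adt_norm.feature_ids, ann)
    if not pairs:
        raise ValidationError("no RNA features with valid ADT pairing")
    rna = rna_norm.to_frame()
    adt = adt_norm.to_frame()
    if cell_subset is not None:
        cells = [c for c in rna.columns if c in set(cell_subset)]
    else:
        cells = [c for c in rna.columns if c in set(adt.columns)]
    if len(cells) < 3:
        raise ValidationError("need at least 3 shared cells")
    records = []
    for rna_id, adt_id in pairs:
        cat = str(ann.loc[rna_id, "category"]) if rna_id in ann.index else "other"
        x = rna.loc[rna_id, cells].to_numpy()
        y = adt.loc[adt_id, cells].to_numpy()
        try:
            rho, p = spearman_rho(x, y)
            records.append(ConcordanceRecord(rna_id, rho, p, len(cells), cat))
        except ValidationError:
            records.append(
                ConcordanceRecord(rna_id, np.nan, np.nan, len(cells), cat, defined=False)
            )
    return records


def gene_level_concordance(
    rna_norm: NormMatrix,
    adt_norm: NormMatrix,
    ann: pd.DataFrame,
    group_by: dict[str, str] | None = None,
) -> tuple[ConcordanceRecord, pd.DataFrame]:
    """Gene-level concordance: one Spearman rho across genes.

    Computes per-gene mean normalized RNA and mean normalized ADT across all
    cells (or, with ``group_by`` mapping cell -> group, pseudobulk means per
    group first, averaged), then correlates the two mean vectors ACROSS
    GENES.  Returns the summary record and the per-gene scatter table.
    """
    pairs = _paired_features(rna_norm.feature_ids, adt_norm.feature_ids, ann)
    if len(pairs) < 3:
        raise ValidationError("gene-level concordance needs >= 3 paired genes")

    def _restored_frame(norm: NormMatrix) -> pd.DataFrame:
        """Per-cell values with any CLR centering constants added back.

        The constant a per-feature CLR subtracts is that feature's mean
        log1p abundance in the cell's sample; the centered values average
        to exactly zero per feature, so gene-level means are only
        meaningful on the restored (log-abundance) scale.
        """
        frame = norm.to_frame()
        if norm.feature_offsets is not None and norm.sample_partition is not None:
            samples = [norm.sample_partition[c] for c in frame.columns]
            frame = frame + norm.feature_offsets.loc[frame.index, samples].to_numpy()
        return frame

    rna = _restored_frame(rna_norm)
    adt = _restored_frame(adt_norm)

    def _mean(frame: pd.DataFrame, fid: str) -> float:
        row = frame.loc[fid]
        if group_by is None:
            return float(row.mean())
        groups = pd.Series({c: group_by[c] for c in frame.columns})
        return float(row.groupby(groups).mean().mean())

    table = pd.DataFrame(
        {
            "feature_id": [r for r, _ in pairs],
            "adt_id": [a for _, a in pairs],
            "mean_rna": [_mean(rna, r) for r, _ in pairs],
            "mean_adt": [_mean(adt, a) for _, a in pairs],
            "category": [str(ann.loc[r, "category"]) for r, _ in pairs],
            "is_cytokine": [bool(ann.loc[r, "is_cytokine"]) for r, _ in pairs],
        }
    ).set_index("feature_id")
    rho, p = spearman_rho(table["mean_rna"], table["mean_adt"])
    record = ConcordanceRecord("__gene_level__", rho, p, len(pairs), "all", level="gene_level_means")
    return record, table


def category_summary(records: list[ConcordanceRecord], ann: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean rho per functional category over records with defined rho.

    Categories whose records are all flagged appear with n = 0 and a
    missing mean.
    """
    if not records:
        raise ValidationError("no concordance records")
    rows = {}
    for rec in records:
        rows.setdefault(rec.category, []).append(rec)
    out = []
    for cat, recs in sorted(rows.items()):
        defined = [r.rho for r in recs if r.defined]
        out.append(
            {
                "category": cat,
                "mean_rho": float(np.mean(defined)) if defined else np.nan,
                "n_features": len(defined),
            }
        )
    return pd.DataFrame(out).set_index("category")


def class_regression(mean_table: pd.DataFrame, ann: pd.DataFrame | None = None) -> list[ClassRegressionResult]:
    """Cytokine vs non-cytokine regression of mean ADT on mean RNA.

    For each class (defined by the ``is_cytokine`` column of the scatter
    table from :func:`gene_level_concordance`): OLS slope and intercept plus
    Spearman rho with its p-value.  A class with fewer than 3 genes yields a
    flagged absent result.
    """
    results = []
    for label, is_cyt in (("cytokine", True), ("non_cytokine", False)):
        sub = mean_table[mean_table["is_cytokine"] == is_cyt]
        if len(sub) < 3:
            results.append(ClassRegressionResult(label, np.nan, np.nan, np.nan, np.nan, len(sub), defined=False))
            continue
        x = sub["mean_rna"].to_numpy()
        y = sub["mean_adt"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        try:
            rho, p = spearman_rho(x, y)
        except ValidationError:
            rho, p = np.nan, np.nan
        results.append(ClassRegressionResult(label, float(slope), float(intercept), rho, p, len(sub)))
    return results


def records_to_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    """Tabulate ConcordanceRecords for export."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "rho": [r.rho for r in records],
            "p_value": [r.p_value for r in records],
            "n": [r.n for r in records],
            "category": [r.category for r in records],
            "level": [r.level for r in records],
            "defined": [r.defined for r in records],
        }
    ).set_index("feature_id")
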