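"""Stimulation-response effect sizes and tests.

Per feature and modality, stimulated vs unstimulated cells are compared
with Cohen's d (pooled SD), Cliff's delta with the conventional
interpretation bins (negligible < 0.147 <= small < 0.33 <= moderate
<= 0.474 < large), log2 fold change of group means, and a two-sided
Wilcoxon rank-sum test with Bonferroni adjustment across the features of a
modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import NormMatrix, ValidationError

__all__ = [
    "EffectRecord",
    "cohens_d",
    "cliffs_delta",
    "cliffs_delta_brute",
    "classify_delta",
    "wilcoxon_rank_sum",
    "bonferroni",
    "log2fc",
    "effect_table",
]

# |delta| bin edges: [0, 0.147) negligible, [0.147, 0.33) small,
# [0.33, 0.474] moderate, (0.474, 1] large
DELTA_BINS = (0.147, 0.33, 0.474)


@dataclass
class EffectRecord:
    """Effect statistics for one feature in one modality (stim - unstim)."""

    feature_id: str
    modality: str  # "rna" | "adt" | "qc_metric"
    cohens_d: float
    cliffs_delta: float
    delta_class: str
    log2fc: float
    p_raw: float
    p_adj: float
    n_stim: int
    n_unstim: int


def cohens_d(a, b) -> float:
    """Cohen's d with pooled sample SD; convention: a = stimulated group.

    ``d = (mean(a) - mean(b)) / s_pooled`` with
    ``s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)``.
    Zero pooled SD gives 0 for equal means and signed infinity otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("cohens_d requires at least 2 values per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


def cliffs_delta(a, b) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-group pairs.

    Computed in O((n+m) log m) with sorted-array bisection; exactly equal to
    the pairwise definition
    ``(#{a_i > b_j} - #{a_i < b_j}) / (n_a * n_b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("cliffs_delta requires non-empty groups")
    b_sorted = np.sort(b)
    greater = np.searchsorted(b_sorted, a, side="left").sum()   # b_j < a_i
    less_eq = len(b) * len(a) - np.searchsorted(b_sorted, a, side="right").sum()  # b_j > a_i
    return float((int(greater) - int(less_eq)) / (len(a) * len(b)))


def cliffs_delta_brute(a, b) -> float:
    """O(n*m) pairwise reference implementation (oracle for testing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


def classify_delta(delta: float) -> str:
    """Interpretation bin of |delta|: negligible / small / moderate / large."""
    mag = abs(float(delta))
    if mag > 1:
        raise ValidationError(f"|delta| must be <= 1, got {delta}")
    lo, mid, hi = DELTA_BINS
    if mag < lo:
        return "negligible"
    if mag < mid:
        return "small"
    if mag <= hi:
        return "moderate"
    return "large"


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with mid-ranks.

    ``mode='exact'`` enumerates all C(n_a + n_b, n_a) group labelings of the
    pooled sample and counts labelings whose rank sum is at least as far
    from its mean as the observed one; only supported without ties.
    ``mode='auto'`` uses exact enumeration when both groups have <= 8 values
    and there are no ties, else the normal approximation with tie and
    continuity corrections.  Returns (rank-sum of a, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("wilcoxon_rank_sum requires non-empty groups")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: len(a)].sum())
    if np.ptp(pooled) == 0:
        return w_obs, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValidationError("exact mode does not support ties")
        n, m = len(a), len(b)
        mean_w = n * (n + m + 1) / 2.0
        obs_dev = abs(w_obs - mean_w)
        count = sum(
            1
            for idx in combinations(range(n + m), n)
            if abs(ranks[list(idx)].sum() - mean_w) >= obs_dev - 1e-9
        )
        return w_obs, count / comb(n + m, n)
    if mode != "normal_approx":
        raise ValidationError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return w_obs, float(res.pvalue)


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.minimum(1.0, m * p)


def log2fc(stim_values, unstim_values, pseudocount: float = 1.0) -> float:
    """log2 fold change of group means with a pseudocount.

    ``log2((mean(stim) + pc) / (mean(unstim) + pc))`` on the normalized or
    count scale; negative means are rejected.
    """
    s = float(np.mean(stim_values))
    u = float(np.mean(unstim_values))
    if s < 0 or u < 0:
        raise ValidationError("log2fc expects non-negative means")
    return float(np.log2((s + pseudocount) / (u + pseudocount)))


def _effect_for_vectors(feature_id: str, modality: str, stim: np.ndarray, unstim: np.ndarray) -> EffectRecord:
    d = cohens_d(stim, unstim)
    delta = cliffs_delta(stim, unstim)
    _, p = wilcoxon_rank_sum(stim, unstim)
    # normalized values can be negative (CLR); shift to a non-negative scale
    shift = min(0.0, float(np.min(stim)), float(np.min(unstim)))
    fc = log2fc(stim - shift, unstim - shift)
    return EffectRecord(
        feature_id, modality, d, delta, classify_delta(delta), fc, p, p, len(stim), len(unstim)
    )


def effect_table(
    rna_norm: NormMatrix | None,
    adt_norm: NormMatrix | None,
    meta: pd.DataFrame,
    ann: pd.DataFrame | None = None,
    features: list[str] | None = None,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Stim-vs-unstim effect statistics per feature x modality.

    Bonferroni m = number of features tested within each modality.  With
    ``cell_type`` given, only cells of that annotated type are compared.
    Returns a DataFrame sorted by |Cohen's d| descending.
    """
    sub = meta if cell_type is None else meta[meta["cell_type"] == cell_type]
    stim_cells = set(sub.index[sub["condition"] == "stimulated"])
    unstim_cells = set(sub.index[sub["condition"] == "unstimulated"])
    if len(stim_cells) < 2 or len(unstim_cells) < 2:
        raise ValidationError("effect_table needs >= 2 cells in each condition")

    rows: list[EffectRecord] = []
    for modality, norm in (("rna", rna_norm), ("adt", adt_norm)):
        if norm is None:
            continue
        frame = norm.to_frame()
        s_cols = [c for c in frame.columns if c in stim_cells]
        u_cols = [c for c in frame.columns if c in unstim_cells]
        if len(s_cols) < 2 or len(u_cols) < 2:
            raise ValidationError(f"{modality}: fewer than 2 cells in a condition")
        feats = features if features is not None else list(frame.index)
        feats = [f for f in feats if f in frame.index]
        records = [
            _effect_for_vectors(f, modality, frame.loc[f, s_cols].to_numpy(), frame.loc[f, u_cols].to_numpy())
            for f in feats
        ]
        p_adj = bonferroni([r.p_raw for r in records], m=len(records))
        for rec, adj in zip(records, p_adj):
            rec.p_adj = float(adj)
        rows.extend(records)

    if not rows:
        raise ValidationError("effect_table: no modality provided")
    table = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "modality": [r.modality for r in rows],
            "cohens_d": [r.cohens_d for r in rows],
            "cliffs_delta": [r.cliffs_delta for r in rows],
            "delta_class": [r.delta_class for r in rows],
            "log2fc": [r.log2fc for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "n_stim": [r.n_stim for r in rows],
            "n_unstim": [r.n_unstim for r in rows],
        }
    )
    table["abs_d"] = table["cohens_d"].abs()
    table = table.sort_values("abs_d", ascending=False).drop(columns="abs_d").reset_index(drop=True)
    return table
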