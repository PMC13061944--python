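"""Cytokine positivity gating and polyfunctionality quadrants.

Positivity thresholds are anchored in control cells (unstimulated, or an
isotype-control matrix): the threshold for a marker is a high quantile of
its normalized ADT values over the controls, so the expected false-positive
rate on controls is 1 - q.  Cells are then classified into the four
quadrants of a two-marker gate (double-negative, each single-positive,
double-positive), and quadrant fractions are tabulated per cell type and
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import NormMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSpec", "adt_threshold", "classify_cells", "fraction_table", "gate_markers"]

QUADRANTS = ("DN", "IFNG_only", "TNF_only", "DP")


@dataclass
class ThresholdSpec:
    """Positivity threshold for one ADT feature, on the CLR scale."""

    feature_id: str
    threshold: float
    method: str = "control_quantile"
    quantile: float = 0.99
    control_n: int = 0


def adt_threshold(control_values, q: float = 0.99, feature_id: str = "") -> ThresholdSpec:
    """Quantile threshold from control cells (linear-interpolation quantile).

    ``q`` is the retained fraction of controls: positivity is defined as a
    value strictly above the threshold, so controls exceed it with expected
    rate 1 - q.
    """
    values = np.asarray(control_values, dtype=float)
    if values.size == 0:
        raise ValidationError("adt_threshold requires non-empty control values")
    if not 0 < q < 1:
        raise ValidationError("quantile q must lie in (0, 1)")
    thr = float(np.quantile(values, q))  # linear interpolation
    return ThresholdSpec(feature_id, thr, "control_quantile", q, int(values.size))


def classify_cells(ifng_values, tnf_values, thr_ifng: float, thr_tnf: float) -> np.ndarray:
    """Quadrant label per cell from two marker vectors and their thresholds.

    Positivity is strict exceedance; values exactly at the threshold count
    as negative.  Labels: DN, IFNG_only, TNF_only, DP.
    """
    x = np.asarray(ifng_values, dtype=float)
    y = np.asarray(tnf_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("marker vectors must have equal length")
    pos_a = x > thr_ifng
    pos_b = y > thr_tnf
    labels = np.where(
        pos_a & pos_b, "DP", np.where(pos_a, "IFNG_only", np.where(pos_b, "TNF_only", "DN"))
    )
    return labels


def fraction_table(labels, meta: pd.DataFrame) -> pd.DataFrame:
    """Quadrant fractions per (cell_type x condition), with marker marginals.

    ``labels`` is a per-cell quadrant Series indexed by cell id (or an array
    aligned to ``meta``).  Output columns: the four quadrant fractions
    (summing to 1 per row), the marginal positive fractions
    (``frac_IFNG_pos = frac_IFNG_only + frac_DP`` and likewise for TNF) and
    the group size.  Empty groups are omitted with a log entry.
    """
    if isinstance(labels, pd.Series):
        missing = [c for c in labels.index if c not in meta.index]
        if missing:
            raise ValidationError(f"labeled cells missing from metadata: {missing[:5]}")
        aligned = labels
    else:
        labels = np.asarray(labels)
        if len(labels) != len(meta):
            raise ValidationError("label vector length does not match metadata")
        aligned = pd.Series(labels, index=meta.index)
    bad = set(aligned.unique()) - set(QUADRANTS)
    if bad:
        raise ValidationError(f"unknown quadrant labels: {sorted(bad)}")

    rows = []
    grouped = meta.loc[aligned.index].groupby(["cell_type", "condition"], observed=True)
    for (cell_type, condition), sub in grouped:
        n = len(sub)
        if n == 0:  # pragma: no cover - groupby omits empty groups
            logger.info("fraction_table: empty group (%s, %s)", cell_type, condition)
            continue
        counts = aligned.loc[sub.index].value_counts()
        frac = {f"frac_{q}": counts.get(q, 0) / n for q in QUADRANTS}
        rows.append(
            {
                "cell_type": cell_type,
                "condition": condition,
                **frac,
                "frac_IFNG_pos": frac["frac_IFNG_only"] + frac["frac_DP"],
                "frac_TNF_pos": frac["frac_TNF_only"] + frac["frac_DP"],
                "n_cells": n,
            }
        )
    return pd.DataFrame(rows)


def gate_markers(
    adt_norm: NormMatrix,
    meta: pd.DataFrame,
    marker_ifng: str,
    marker_tnf: str,
    q: float = 0.99,
    control_meta: pd.DataFrame | None = None,
    per_sample: bool = True,
) -> tuple[pd.Series, pd.DataFrame, list[ThresholdSpec]]:
    """End-to-end gating: thresholds from unstimulated controls, then quadrants.

    Thresholds are computed per sample (matching per-sample CLR) from that
    sample's unstimulated cells; samples without unstimulated cells fall
    back to the pooled controls.  Returns (per-cell labels, fraction table,
    thresholds).
    """
    frame = adt_norm.to_frame()
    for marker in (marker_ifng, marker_tnf):
        if marker not in frame.index:
            raise ValidationError(f"marker {marker!r} not in ADT features")
    meta = meta.loc[[c for c in frame.columns if c in meta.index]]
    if len(meta) != frame.shape[1]:
        raise ValidationError("ADT matrix contains cells missing from metadata")
    controls = control_meta if control_meta is not None else meta[meta["condition"] == "unstimulated"]
    if controls.empty:
        raise ValidationError("no control (unstimulated) cells available")

    labels = pd.Series(index=meta.index, dtype=object)
    specs: list[ThresholdSpec] = []
    samples = meta["sample_id"].unique() if per_sample else ["__all__"]
    for s in samples:
        cells = meta.index if s == "__all__" else meta.index[meta["sample_id"] == s]
        ctrl = [c for c in cells if c in controls.index]
        if not ctrl:
            ctrl = list(controls.index)
        thr_i = adt_threshold(frame.loc[marker_ifng, ctrl], q, marker_ifng)
        thr_t = adt_threshold(frame.loc[marker_tnf, ctrl], q, marker_tnf)
        specs += [thr_i, thr_t]
        labels.loc[cells] = classify_cells(
            frame.loc[marker_ifng, cells], frame.loc[marker_tnf, cells],
            thr_i.threshold, thr_t.threshold,
        )
    return labels, fraction_table(labels, meta), specs
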