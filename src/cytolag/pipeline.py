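"""Configuration-driven orchestration of the full analysis.

A pipeline run starts either from files (MTX triplets + metadata tables) or
from the simulator, then proceeds qc/filter -> normalize -> concordance ->
effects -> polyfunc -> lag, writing each stage's tables before the next
begins.  Everything is deterministic given the config and seed; the run
manifest records the package version, a hash of the effective
configuration, the seed, and per-stage cell/feature counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError, model_validator

from ._version import __version__ as _pkg_version
from .io_qc import (
    NormMatrix,
    QCMetrics,
    ValidationError,
    clr_normalize,
    compute_qc,
    filter_cells,
    lognorm,
    read_counts,
    read_table,
    validate_cell_meta,
    validate_feature_annotation,
    write_counts,
    write_table,
)
from .simulate import SimConfig, simulate_cells
from .concordance import (
    category_summary,
    class_regression,
    gene_level_concordance,
    per_gene_cell_correlation,
    records_to_frame,
)
from .effects import effect_table
from .polyfunc import gate_markers
from .pseudolag import rna_protein_kinetics

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "normalize", "concordance", "effects", "polyfunc", "lag")

STAGE_DEPS = {
    "normalize": ("qc",),
    "concordance": ("normalize",),
    "effects": ("normalize",),
    "polyfunc": ("normalize",),
    "lag": ("normalize",),
}


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rna: str
    adt: str
    meta: str
    annotation: str


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = 3000
    stim_fraction: float = 0.5
    pi_mito: float = 0.08
    n_genes: int = 300
    n_mito_genes: int = 13
    ambient_adt: float = 0.5
    adt_gain: float = 5.0
    nb_dispersion: float = 0.15
    n_samples: int = 1


class FilterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_features: int = 200
    max_features: int = 8000
    max_pct_mito: float = 20.0


class PolyfuncParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    marker_ifng: str = "IFNG-ADT"
    marker_tnf: str = "TNF-ADT"
    quantile: float = 0.99


class LagParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene: str = "IFNG"
    use_true_pseudotime: bool = False
    k: int = 15
    n_pcs: int = 20
    n_grid: int = 101
    bandwidth: float = 0.08
    max_lag_steps: int = 30


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    input: InputPaths | None = None
    simulate: SimulateBlock | None = None
    stages: list[str] = list(ALL_STAGES)
    filters: FilterParams = FilterParams()
    polyfunc: PolyfuncParams = PolyfuncParams()
    lag: LagParams = LagParams()
    seed: int | None = None
    outdir: str = "cytolag_output"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' and 'simulate' must be given")
        if self.simulate is not None and self.seed is None:
            raise ValueError("seed is mandatory when simulate is used")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return self

    def effective_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        """Hash of the effective analysis parameters (outdir excluded: it
        changes where results go, not what they are)."""
        eff = self.effective_dict()
        eff.pop("outdir", None)
        blob = json.dumps(eff, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a YAML/JSON config document (or a dict)."""
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as e:
            raise ValidationError(f"unparseable config: {e}") from e
    else:
        data = raw
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    try:
        return PipelineConfig(**data)
    except PydanticValidationError as e:
        raise ValidationError(str(e)) from e


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed so toggling one stage leaves others fixed."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run, mirroring the files on disk."""

    qc_summary: dict = field(default_factory=dict)
    qc: QCMetrics | None = None
    concordance_records: pd.DataFrame | None = None
    gene_level_scatter: pd.DataFrame | None = None
    category_summary: pd.DataFrame | None = None
    class_regression: pd.DataFrame | None = None
    effects: pd.DataFrame | None = None
    polyfunctionality: pd.DataFrame | None = None
    thresholds: pd.DataFrame | None = None
    pseudotime: pd.Series | None = None
    lag_report: dict | None = None
    manifest: dict = field(default_factory=dict)
    rna_norm: NormMatrix | None = None
    adt_norm: NormMatrix | None = None
    meta: pd.DataFrame | None = None
    ann: pd.DataFrame | None = None


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_cfg = SimConfig(seed=derive_seed(config.seed, "simulate"), **config.simulate.model_dump())
        sim = simulate_cells(sim_cfg)
        return sim.rna, sim.adt, sim.meta, sim.ann, sim
    paths = config.input
    rna = read_counts(paths.rna, "rna")
    adt = read_counts(paths.adt, "adt")
    meta = validate_cell_meta(read_table(paths.meta))
    ann = validate_feature_annotation(read_table(paths.annotation), adt.feature_ids)
    return rna, adt, meta, ann, None


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the configured stages in order, writing outputs as they complete.

    Raises :class:`ValidationError` when a requested stage's dependency is
    not enabled.  The manifest is written last (or, on failure, with the
    failing stage recorded before the exception propagates).
    """
    for stage in config.stages:
        for dep in STAGE_DEPS.get(stage, ()):
            if dep not in config.stages:
                raise ValidationError(f"stage {stage!r} requires stage {dep!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    manifest: dict[str, Any] = {
        "version": _pkg_version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
    }
    bundle.manifest = manifest
    current = "load"
    try:
        rna, adt, meta, ann, sim = _load_inputs(config)
        meta = validate_cell_meta(meta)
        ann = validate_feature_annotation(ann, adt.feature_ids)
        if sim is not None:
            write_counts(rna, outdir / "rna")
            write_counts(adt, outdir / "adt")
            write_table(meta, outdir / "meta.tsv")
            write_table(ann, outdir / "annotation.tsv")
            sim.truth.to_json(outdir / "truth.json")
        manifest["counts"]["load"] = {"cells": rna.n_cells, "rna_features": rna.n_features, "adt_features": adt.n_features}

        if "qc" in config.stages:
            current = "qc"
            qc = compute_qc(rna, ann)
            keep, summary = filter_cells(qc, **config.filters.model_dump())
            rna = rna.subset_cells(keep)
            adt = adt.subset_cells(keep)
            meta = meta.loc[rna.cell_ids]
            write_table(qc, outdir / "qc.tsv")
            _write_json(summary, outdir / "filter_summary.json")
            bundle.qc, bundle.qc_summary = qc, summary
            manifest["counts"]["qc"] = {"cells_kept": int(keep.sum())}

        rna_norm = adt_norm = None
        if "normalize" in config.stages:
            current = "normalize"
            rna_norm = lognorm(rna)
            adt_norm = clr_normalize(adt, dict(zip(meta.index, meta["sample_id"])))
            bundle.rna_norm, bundle.adt_norm = rna_norm, adt_norm
            manifest["counts"]["normalize"] = {"cells": rna_norm.n_cells}

        if "concordance" in config.stages:
            current = "concordance"
            records = per_gene_cell_correlation(rna_norm, adt_norm, ann)
            rec_frame = records_to_frame(records)
            gene_record, scatter = gene_level_concordance(rna_norm, adt_norm, ann)
            cats = category_summary(records)
            regs = class_regression(scatter)
            reg_frame = pd.DataFrame([asdict(r) for r in regs]).set_index("class_label")
            write_table(rec_frame, outdir / "per_gene_concordance.tsv")
            write_table(scatter, outdir / "gene_level_scatter.tsv")
            write_table(cats, outdir / "category_summary.tsv")
            write_table(reg_frame, outdir / "class_regression.tsv")
            _write_json(
                {"gene_level_rho": gene_record.rho, "gene_level_p": gene_record.p_value, "n_genes": gene_record.n},
                outdir / "gene_level_concordance.json",
            )
            bundle.concordance_records = rec_frame
            bundle.gene_level_scatter = scatter
            bundle.category_summary = cats
            bundle.class_regression = reg_frame
            manifest["counts"]["concordance"] = {"paired_genes": len(rec_frame)}

        if "effects" in config.stages:
            current = "effects"
            eff = effect_table(rna_norm, adt_norm, meta, ann)
            write_table(eff, outdir / "effects.tsv", index=False)
            bundle.effects = eff
            manifest["counts"]["effects"] = {"tests": len(eff)}

        if "polyfunc" in config.stages:
            current = "polyfunc"
            pf = config.polyfunc
            labels, fractions, specs = gate_markers(
                adt_norm, meta, pf.marker_ifng, pf.marker_tnf, q=pf.quantile
            )
            thr = pd.DataFrame([asdict(s) for s in specs]).set_index("feature_id")
            write_table(fractions, outdir / "polyfunctionality.tsv", index=False)
            write_table(thr, outdir / "thresholds.tsv")
            bundle.polyfunctionality, bundle.thresholds = fractions, thr
            manifest["counts"]["polyfunc"] = {"cells_gated": int(len(labels))}

        if "lag" in config.stages:
            current = "lag"
            lp = config.lag
            true_t = None
            if lp.use_true_pseudotime:
                if "true_pseudotime" not in meta.columns:
                    raise ValidationError("use_true_pseudotime requires a true_pseudotime column")
                true_t = meta["true_pseudotime"]
            lag, rna_curve, prot_curve, pt = rna_protein_kinetics(
                rna_norm, adt_norm, meta, lp.gene,
                pseudotime=true_t, k=lp.k, n_pcs=lp.n_pcs,
                n_grid=lp.n_grid, bandwidth=lp.bandwidth, max_lag_steps=lp.max_lag_steps,
            )
            if pt is not None:
                write_table(pt.t.to_frame(), outdir / "pseudotime.tsv")
                bundle.pseudotime = pt.t
            report = {
                "gene": lp.gene,
                "delta_peak": lag.delta_peak,
                "lag_max_corr": lag.lag_max_corr,
                "max_corr": lag.max_corr,
                "grid_spacing": lag.grid_spacing,
                "used_true_pseudotime": lp.use_true_pseudotime,
            }
            _write_json(report, outdir / "lag_report.json")
            curves = pd.DataFrame(
                {"grid": rna_curve.grid, "rna": rna_curve.values, "protein": prot_curve.values}
            )
            write_table(curves, outdir / "lag_curves.tsv", index=False)
            bundle.lag_report = report
            manifest["counts"]["lag"] = {"grid": lp.n_grid}
    except Exception:
        manifest["failed_at"] = current
        _write_json(manifest, outdir / "manifest.json")
        raise

    bundle.meta, bundle.ann = meta, ann
    _write_json(manifest, outdir / "manifest.json")
    return bundle
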