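# cytolag

Analysis toolkit for **paired single-cell RNA + intracellular protein (ADT)
data** of the kind produced by intracellular CITE-seq protocols: PBMC-style
populations measured before and after pharmacological stimulation, with an
antibody panel reading out intracellular proteins (cytokines in particular)
alongside the transcriptome.

The package answers four questions such experiments pose:

1. **How well does RNA predict intracellular protein?** Per-gene Spearman ρ
   across cells, gene-level ρ across per-gene means (mean log-normalized
   UMI vs mean CLR-normalized ADT), category averages, and separate
   cytokine / non-cytokine regressions — cytokines are expected to show
   lower ρ and flatter slopes than other genes.
2. **Which features respond to stimulation, and how strongly?** Cohen's
   *d*, Cliff's δ with the conventional interpretation bins
   (|δ| < 0.147 negligible, < 0.33 small, ≤ 0.474 moderate, > 0.474 large),
   log₂ fold change, and two-sided Wilcoxon rank-sum tests with Bonferroni
   correction, per feature and modality.
3. **How polyfunctional are the responding cells?** Control-anchored
   positivity thresholds on CLR-normalized ADT and quadrant classification
   (double-negative / IFNG-only / TNF-only / double-positive) per cell type
   and condition.
4. **Does transcription lead protein accumulation?** A deterministic graph
   pseudotime (PCA → kNN graph → shortest paths from a root anchored in
   unstimulated cells), Nadaraya–Watson smoothing of both modalities along
   it, and two timing statistics in pseudotime units: Δpeak (protein peak
   position − RNA peak position) and the cross-correlation lag (positive =
   RNA leads protein).

Because public deposits of such data are large and protocol-specific, the
package ships a first-class **synthetic data generator**: paired
negative-binomial counts whose RNA and ADT channels follow logistic
activation curves along a latent pseudotime, with per-gene protein lag,
Gaussian-copula RNA–protein coupling (so the implied Spearman ρ has the
closed form (6/π)·arcsin(c/2)), cytokine/non-cytokine classes, stim/unstim
conditions, and a tunable expected mitochondrial count share emulating
fixation stress. Every downstream statistic therefore has a planted ground
truth to recover.

## Worked example

```python
from cytolag import (SimConfig, simulate_cells, compute_qc, filter_cells,
                     lognorm, clr_normalize, gene_level_concordance,
                     class_regression, rna_protein_kinetics)

sim = simulate_cells(SimConfig(seed=1))          # 3000 cells, 300 genes + ADT panel
qc = compute_qc(sim.rna, sim.ann)
keep, summary = filter_cells(qc)                 # <200 / >8000 genes, >20% mito
rna = lognorm(sim.rna.subset_cells(keep))
adt = clr_normalize(sim.adt.subset_cells(keep), sim.sample_of)

record, scatter = gene_level_concordance(rna, adt, sim.ann)
print(f"gene-level rho = {record.rho:.3f} (n = {record.n} genes)")
for r in class_regression(scatter):
    print(f"{r.class_label}: rho = {r.rho:.2f}, slope = {r.slope:.2f}")

i = sim.truth.gene_ids.index("TNF")
print(f"planted TNF lag = {sim.truth.lag[i]:.3f}")
lag, *_ = rna_protein_kinetics(rna, adt, sim.meta, "TNF",
                               pseudotime=sim.meta["true_pseudotime"])
print(f"TNF lag = {lag.lag_max_corr:.3f}, delta-peak = {lag.delta_peak:.3f}")
```

Output (seed 1):

```
gene-level rho = 0.709 (n = 300 genes)
cytokine: rho = 0.44, slope = 0.82
non_cytokine: rho = 0.80, slope = 0.93
planted TNF lag = 0.072
TNF lag = 0.049, delta-peak = 0.170
```

Per-gene protein abundance tracks RNA abundance overall (ρ = 0.71 across
genes), but the cytokine class — simulated with wide translation-efficiency
noise and weaker cell-level coupling — shows the markedly lower ρ that
real intracellular panels show. The TNF protein channel lags its RNA
channel along the true activation time (planted 0.072, recovered 0.049 at
this seed; single-gene lag estimates carry ~0.01–0.02 pseudotime units of
spread, see `docs/methods.md`), and Δpeak > 0 confirms RNA rises first.

There is also a CLI over the same pipeline:

```bash
cytolag run-all --seed 1 --outdir out/      # simulate + every stage
cytolag simulate --seed 1 --outdir data/    # just write a synthetic dataset
cytolag lag --config my_config.yaml         # one stage, from a config file
```

`run-all` writes MTX count triplets, QC and concordance tables (TSV), the
effect-size table, polyfunctionality fractions, per-cell pseudotime, a lag
report (JSON) and a manifest with the config hash — the whole tree is
byte-identical when re-run with the same seed.

## Layout

| module | contents |
| --- | --- |
| `cytolag.io_qc` | count-matrix IO (MTX/CSV), QC metrics, cell filters, log / CLR normalization |
| `cytolag.simulate` | copula-coupled negative-binomial generator with ground truth |
| `cytolag.concordance` | Spearman machinery, per-gene and gene-level concordance, class regression |
| `cytolag.effects` | Cohen's d, Cliff's δ (+ bins), Wilcoxon, Bonferroni, log₂FC, effect tables |
| `cytolag.polyfunc` | control-quantile gating and quadrant fractions |
| `cytolag.pseudolag` | graph pseudotime, curve smoothing, Δpeak, cross-correlation lag |
| `cytolag.pipeline` / `cytolag.cli` | config validation, orchestration, CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
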