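# Methods

This note documents the statistical model behind `cytolag`, the defaults it
ships, and the reasoning behind the choices that were genuinely open.

## Data model and normalization

A dataset is a pair of integer feature × cell count matrices — RNA and
ADT (antibody-derived tags reading out intracellular protein) — plus cell
metadata (sample, stimulated/unstimulated condition, cell-type label) and
feature annotation (mitochondrial flag, functional category, RNA↔ADT
pairing).

**QC.** Per cell: detected features, total counts, and mitochondrial
percentage (100 × mito counts / total counts; defined as 0 and flagged for
empty cells). Cells are excluded when they have **strictly fewer than 200**
detected features, **strictly more than 8,000**, or **strictly more than
20%** mitochondrial counts; boundary values are retained because the
exclusion rules are written as strict inequalities. More stringent
mitochondrial cutoffs (15%, 10%) are available as parameters for
stress-focused sensitivity analyses.

**RNA normalization** is counts-per-10,000 followed by ln(1+x)
(`lognorm_cp10k`). SCTransform-style variance stabilization is out of
scope. Zero-total cells are dropped with a warning rather than raising, so
small fixtures remain usable.

**ADT normalization** is a centered log-ratio per **feature** across the
cells of each **sample**: clr(f,c) = ln(1+n(f,c)) − mean over the sample's
cells of ln(1+n(f,·)). The pseudocount (+1), natural log, and the
per-feature margin are package choices; the alternative margin (per cell
across features) is deliberately rejected because antibody panels are small
and compositional closure across a ~50–300-plex panel distorts
high-abundance targets. A single-cell sample yields all-zero CLR values and
a warning. Within one sample, CLR is a monotone transform of the raw
count, which several rank-based results below rely on.

## The synthetic study

The generator emulates a stimulated-vs-unstimulated PBMC experiment with an
intracellular panel. Its defaults *are* the study conditions; they were
chosen once, on the grounds below, and all recovery tests run at them.

* **Latent activation pseudotime** t ∈ [0,1] per cell: Beta(1,8) for
  unstimulated cells (resting cells pile up near 0), Beta(2,2) rescaled to
  [0.2,1] for stimulated cells. 3,000 cells, half stimulated.
* **Activation curves**: gene g has rate b·(1 + a·σ((t−τ)/w)) with σ the
  logistic function. A monotone induction (rather than a transient bump)
  reflects secretion-blocked intracellular accumulation over a short
  stimulation; protein plateaus rather than peaking. Baselines b are
  lognormal(ln 6, 0.5) — a well-expressed targeted panel; midpoints τ tile
  U(0.02, 0.9) so that immediate-early through late response genes cover
  the whole trajectory (this is what makes every stretch of latent time
  identifiable, as in a real global PMA/ionomycin-style response); widths
  w ~ U(0.04, 0.15).
* **Gene classes**: 25% cytokines (a ~ U(2,4), protein lag λ ~ U(0.02,0.08),
  weaker RNA–protein coupling c ~ U(0.2,0.45)); 70% of the remainder mildly
  responsive (a ~ U(0.5,2)); the rest flat. Non-cytokine coupling
  c ~ U(0.4,0.8). 300 genes by default so that the ≥200-detected-genes
  filter is meaningful.
* **Protein channel**: the same activation curve evaluated at t−λ (clipped
  to [0,1]), times an ADT gain of 5 (tag counts run higher than UMIs) and a
  per-gene translation-efficiency factor (lognormal; σ = 0.9 for cytokines
  vs 0.35 otherwise — post-transcriptional regulation decouples mean
  protein from mean RNA far more for cytokines), plus an ambient
  background rate of 0.5.
* **Counts**: negative binomial with Var = μ + 0.15·μ² (a mid-range UMI
  dispersion). Within a gene, the RNA and ADT draws of a cell share a
  Gaussian copula with correlation c, so the implied Spearman correlation
  has the closed form (6/π)·arcsin(c/2) — chosen over additive shared noise
  precisely because this target is exact. The identity holds only for flat
  genes (a=0): activation along the shared pseudotime adds dependence on
  top of the copula, so coupling-recovery experiments use flat panels.
* **Mitochondrial stress**: mito genes are drawn so each cell's expected
  mito share equals π_mito (default 0.08). The two-protocol fixture
  reuses one gene-level truth with two π values; π is a phenomenological
  stress knob, not an estimate of any particular chemistry's effect.

All randomness flows from one seeded generator; identical (config, truth,
seed) gives bitwise-identical output.

## Concordance statistics

Spearman ρ uses mid-ranks for ties; p-values come from the Student-t
approximation t = ρ√((n−2)/(1−ρ²)) (exact permutation enumeration is
available for n ≤ 10); ρ = ±1 snaps exactly and reports p = 0. Undefined ρ
(constant input) yields a flagged record, never an imputed 0, and category
means average defined records only.

Gene-level concordance correlates per-gene mean normalized RNA with
per-gene mean normalized ADT **across genes**, over all cells by default
(an option aggregates within sample pseudobulk first — the right unit when
samples are heterogeneous). One subtlety is forced by the CLR margin: a
per-feature CLR averages to exactly zero for every feature, so a "mean
CLR" per gene is degenerate by construction. The gene-level ADT mean
therefore restores the per-(feature, sample) centering constant that CLR
subtracted — i.e., it is the mean log1p tag abundance, the scale on which
a gene-level RNA-vs-protein scatter is meaningful ( `clr_normalize`
stores these constants on the normalized matrix for this purpose). Cytokine and non-cytokine classes additionally
get OLS fits of mean ADT on mean RNA; the expected signature of weak
cytokine RNA–protein coupling is a lower class ρ.  (On synthetic data the
class slopes stay comparable: translation-efficiency noise lowers
correlation but leaves the OLS slope unbiased; a genuinely flatter
cytokine slope requires saturating translation, which the generator does
not model.)

## Effect sizes

Cohen's d uses the pooled-SD (Student) form, direction stimulated −
unstimulated; Hedges' correction is not applied. Cliff's δ is computed by
sorted-array bisection in O((n+m) log m) and agrees exactly with the
pairwise definition; the interpretation bins are half-open:
[0, 0.147) negligible, [0.147, 0.33) small, [0.33, 0.474] moderate,
(0.474, 1] large (the conventional printed ranges do not specify edge
ownership; this assignment is the package's). Wilcoxon rank-sum p-values
are exact by full enumeration for groups of ≤ 8 without ties, otherwise a
normal approximation with tie and continuity corrections. Bonferroni
multiplies by the number of features tested within a modality.

log₂ fold changes use a pseudocount of 1 on the normalized scale; in the
assembled effect table, CLR values (which can be negative) are shifted by
their group minimum before the ratio — fold changes on a centered scale
are otherwise undefined.

One property worth knowing: a flat gene inside a globally activated panel
is **not** null after library-size normalization — rising cell totals
depress its normalized values in stimulated cells. This compositional
effect is real, not a bug; false-positive-rate checks therefore use
all-flat panels.

## Polyfunctionality gating

The positivity threshold for a marker is the q-quantile
(linear-interpolation) of its normalized values over control cells —
unstimulated cells by default, an isotype-control matrix if supplied —
with q = 0.99, i.e. a 1% false-positive budget on controls. Positivity is
strict exceedance (ties are negative, the conservative call). Thresholds
are computed per sample, matching per-sample CLR. Quadrant fractions
(DN / IFNG-only / TNF-only / DP) are tabulated per cell type × condition;
marginal positive fractions count DP in both markers. Mixture-model or
density-based automatic gating is deliberately out of scope.

## Pseudotime and the RNA→protein lag

**Pseudotime.** Per-feature standardized expression → PCA (20 components,
matching common practice) → symmetric kNN graph (k = 15, Euclidean edge
weights in PC space) → Dijkstra shortest-path distance from a root cell →
divide by the maximum over reachable cells. Unreachable cells are flagged,
never imputed. Two numerical choices matter:

* *Eigenvalue shrinkage.* On a ~300-feature panel, most of the 20 PCs are
  noise, and their summed variance rivals the leading component, so raw
  Euclidean edges are noise-dominated. Each PC is rescaled to its signal
  variance max(0, λᵢ − median λ) before graph construction (skipped below
  3 components, where no noise floor exists). This is ordinary
  random-matrix denoising and raised latent-time recovery from ≈0.94 to
  ≈0.97 Spearman on default synthetic data.
* *Root placement.* The root is the medoid of the 5% of unstimulated cells
  farthest (in PC space) from the stimulated medoid — the resting *end* of
  the trajectory, robust to single outliers. Rooting at the plain
  unstimulated medoid would start the walk in the middle of the resting
  cloud and invert the ordering of every cell earlier than it.

**Smoothing.** Nadaraya–Watson with a Gaussian kernel on a uniform grid of
101 points over [0,1] (spacing exactly 0.01), bandwidth h = 0.05 for
display purposes and h = 0.08 inside the lag estimator; grid points with
total kernel weight < 1e-8 are flagged empty.

**Δpeak** is the protein peak position minus the RNA peak position, where
the "peak" of a monotone (plateau) curve is the earliest grid point
reaching 95% of the curve's range above its minimum — a literal argmax is
tie-degenerate on plateaus. Flat curves give an undefined (NaN) result.

**Cross-correlation lag**: Pearson correlation between the overlapping
segments of the two mean-centered curves at each integer grid shift in
[−30, 30], RNA shifted forward, so positive lag = RNA leads protein. Ties
resolve to the smallest |shift|, then positive. The reported lag is
refined by quadratic interpolation of the correlation profile around its
maximum (the profile of two near-monotone curves is smooth and extremely
flat, so the continuous vertex is both less noisy and less quantized than
the raw grid argmax; the refinement is clamped to ±1 grid step).

`rna_protein_kinetics` applies a rank-based inverse-normal transform to
each modality before smoothing. This matters: log-CP10K and CLR distort
the same underlying sigmoid differently (cell totals rise with activation
and flatten the RNA curve top), and aligning raw normalized curves
systematically overestimates the lag by ~0.01–0.02 pseudotime units. On
the common rank scale the two curves differ only by the kinetic shift. It
also excludes the queried gene from pseudotime inference (leave-one-out):
a strongly induced readout gene otherwise helps build the axis its own
curve is compared against, and the resulting self-selection bias is
asymmetric between modalities.

**Units.** Lags are in pseudotime units, which are only defined up to the
monotone warp of the inferred axis. On default synthetic data the inferred
axis compresses a planted lag of 0.05 true-time units to ≈0.03 inferred
units even for noiseless signals; recovery bands for inferred-time lags
are correspondingly wider than for true-time lags, and a lag estimated on
an inferred axis should never be read as a wall-clock quantity.

The lag is only estimable for genes whose activation sits in the
trajectory interior: a rise too close to t = 1 is partially observed and
its alignment is unstable.

## Pipeline and reproducibility

A validated config (unknown keys rejected; exactly one of file-input or
simulate block; seed mandatory when simulating) drives the stage order
simulate/read → qc/filter → normalize → concordance → effects → polyfunc →
lag, each stage writing its tables before the next begins. One base seed
fans out to per-stage child seeds by a fixed CRC-based derivation, so
toggling one stage does not perturb another's randomness. The manifest
records the package version, seed, per-stage counts, and a hash of the
effective analysis parameters (the output directory is excluded — it
changes where results go, not what they are). Identical config + seed
produces a byte-identical output tree.

Problem sizes used in the shipped tests and acceptance script — 300–3,000
cells, 60–300 genes, 3–20 seed replicates per claim — were chosen as the
smallest sizes at which the targeted effects are comfortably resolved by
the statistics involved.

## Known limitations

* The generator has no ambient-RNA soup, doublets, batch effects,
  cell-cycle structure, or branching trajectories; passing recovery tests
  says nothing about robustness to those.
* Monotone activation means Δpeak relies on the rise-point convention; for
  genuinely peaked dynamics a literal argmax would differ.
* CLR across samples makes stim-vs-unstim ADT comparisons meaningful only
  when conditions are pooled within samples; fully condition-confounded
  samples would have their mean shift absorbed by the centering.
* The Wilcoxon normal approximation is used whenever groups exceed 8 or
  contain ties; exact mid-p alternatives are not implemented.
* Pseudotime units are not calibrated to wall-clock time, and lag
  estimates inherit the monotone warp of the inferred axis (see above).
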