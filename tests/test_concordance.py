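import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytolag.concordance import (
    ConcordanceRecord,
    category_summary,
    class_regression,
    gene_level_concordance,
    per_gene_cell_correlation,
    spearman_rho,
)
from cytolag.io_qc import ValidationError, clr_normalize, lognorm
from cytolag.simulate import SimConfig, simulate_cells


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)
        assert spearman_rho(x, np.exp(x))[1] == 0.0

    def test_hand_ranked_ties_example(self):
        rho, _ = spearman_rho([1, 2, 2, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5))

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        from scipy import stats

        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # perfectly concordant n=4: one-in-24 permutations at least as extreme...
        # both +1 and -1 orderings reach |rho| = 1, so p = 2/24
        rho, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40], exact=True)
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True))
    def test_invariant_under_increasing_transform(self, ints):
        x = np.asarray(ints, dtype=float) / 10.0
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(x))
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x / 100.0), y)  # strictly increasing
        assert rho1 == pytest.approx(rho2)


@pytest.fixture(scope="module")
def normed_sim():
    sim = simulate_cells(SimConfig(n_cells=600, seed=13))
    return sim, lognorm(sim.rna), clr_normalize(sim.adt, sim.sample_of)


class TestPerGene:
    def test_records_cover_paired_features(self, normed_sim):
        sim, rn, an = normed_sim
        records = per_gene_cell_correlation(rn, an, sim.ann)
        assert len(records) == sim.truth.n_genes
        assert all(abs(r.rho) <= 1 for r in records if r.defined)

    def test_permuted_adt_kills_correlation(self, normed_sim):
        sim, rn, an = normed_sim
        rng = np.random.default_rng(0)
        perm = rng.permutation(an.n_cells)
        from cytolag.io_qc import NormMatrix

        an_perm = NormMatrix(an.values[:, perm], an.feature_ids, an.cell_ids, an.method)
        records = per_gene_cell_correlation(rn, an_perm, sim.ann)
        mean_abs = np.mean([abs(r.rho) for r in records if r.defined])
        assert mean_abs < 0.08

    def test_constant_adt_flagged(self, normed_sim):
        sim, rn, an = normed_sim
        from cytolag.io_qc import NormMatrix

        vals = an.values.copy()
        vals[0, :] = 0.0
        an2 = NormMatrix(vals, an.feature_ids, an.cell_ids, an.method)
        records = per_gene_cell_correlation(rn, an2, sim.ann)
        rec = next(r for r in records if r.feature_id == sim.truth.gene_ids[0])
        assert not rec.defined

    def test_empty_pairing_errors(self, normed_sim):
        sim, rn, an = normed_sim
        ann = sim.ann.copy()
        ann["paired_adt_id"] = None
        with pytest.raises(ValidationError):
            per_gene_cell_correlation(rn, an, ann)


class TestGeneLevel:
    def test_hand_rank_example(self, normed_sim):
        sim, rn, an = normed_sim
        # plant per-gene means with known ranks: RNA (1..5), ADT (2,1,4,3,5);
        # rank differences d = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        from cytolag.io_qc import NormMatrix

        genes = sim.truth.gene_ids[:5]
        ann = sim.ann.loc[list(genes) + [f"{g}-ADT" for g in genes]].copy()
        n_cells = rn.n_cells
        rna_vals = np.tile(np.array([1.0, 2, 3, 4, 5])[:, None], (1, n_cells))
        adt_vals = np.tile(np.array([2.0, 1, 4, 3, 5])[:, None], (1, n_cells))
        rn2 = NormMatrix(rna_vals, list(genes), rn.cell_ids, "lognorm_cp10k")
        an2 = NormMatrix(adt_vals, [f"{g}-ADT" for g in genes], an.cell_ids, "clr_per_feature")
        record, table = gene_level_concordance(rn2, an2, ann)
        from scipy import stats as sps

        assert record.rho == pytest.approx(1 - 6 * 4 / (5 * 24))  # = 0.8
        assert record.rho == pytest.approx(
            sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]).statistic
        )
        assert record.level == "gene_level_means"
        assert len(table) == 5

    def test_modality_swap_symmetric(self, normed_sim):
        sim, rn, an = normed_sim
        record, _ = gene_level_concordance(rn, an, sim.ann)
        # swap roles by building a reversed annotation
        ann_swapped = sim.ann.copy()
        rev = {f"{g}-ADT": g for g in sim.truth.gene_ids}
        ann_swapped["paired_adt_id"] = [rev.get(f) for f in ann_swapped.index]
        record_swapped, _ = gene_level_concordance(an, rn, ann_swapped)
        assert record_swapped.rho == pytest.approx(record.rho)

    def test_too_few_pairs_errors(self, normed_sim):
        sim, rn, an = normed_sim
        ann = sim.ann.copy()
        keep = sim.truth.gene_ids[:2]
        ann.loc[~ann.index.isin(keep), "paired_adt_id"] = None
        with pytest.raises(ValidationError, match=">= 3"):
            gene_level_concordance(rn, an, ann)


class TestCategorySummary:
    def test_hand_average(self):
        records = [
            ConcordanceRecord("g1", 0.2, 0.5, 100, "a"),
            ConcordanceRecord("g2", 0.4, 0.5, 100, "a"),
            ConcordanceRecord("g3", -0.1, 0.5, 100, "b"),
        ]
        out = category_summary(records)
        assert out.loc["a", "mean_rho"] == pytest.approx(0.3)
        assert out.loc["b", "mean_rho"] == pytest.approx(-0.1)
        assert out.loc["a", "n_features"] == 2

    def test_flagged_only_category(self):
        records = [
            ConcordanceRecord("g1", np.nan, np.nan, 10, "bad", defined=False),
            ConcordanceRecord("g2", 0.5, 0.01, 10, "good"),
        ]
        out = category_summary(records)
        assert out.loc["bad", "n_features"] == 0
        assert np.isnan(out.loc["bad", "mean_rho"])

    def test_means_within_member_range(self, normed_sim):
        sim, rn, an = normed_sim
        records = per_gene_cell_correlation(rn, an, sim.ann)
        out = category_summary(records)
        for cat, row in out.iterrows():
            members = [r.rho for r in records if r.category == cat and r.defined]
            if members:
                assert min(members) <= row["mean_rho"] <= max(members)


class TestClassRegression:
    def test_exact_line(self):
        table = pd.DataFrame(
            {
                "mean_rna": [0.0, 1.0, 2.0, 0.5, 1.5, 2.5],
                "mean_adt": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
                "is_cytokine": [True, True, True, False, False, False],
            }
        )
        results = {r.class_label: r for r in class_regression(table)}
        assert results["cytokine"].slope == pytest.approx(2.0)
        assert results["cytokine"].intercept == pytest.approx(1.0)
        assert results["non_cytokine"].rho == pytest.approx(1.0)

    def test_small_class_flagged_absent(self):
        table = pd.DataFrame(
            {
                "mean_rna": [0.0, 1.0, 2.0, 3.0],
                "mean_adt": [1.0, 3.0, 5.0, 9.0],
                "is_cytokine": [True, False, False, False],
            }
        )
        results = {r.class_label: r for r in class_regression(table)}
        assert not results["cytokine"].defined
        assert results["non_cytokine"].defined

    def test_low_coupling_class_has_lower_rho_and_flatter_slope(self):
        """Cytokines simulated with weaker coupling and wider
        translation-efficiency noise show the expected qualitative
        contrast at both levels: lower per-gene cell-level rho and lower
        gene-level class rho.  (The regression slope is not asserted:
        noise in the protein means lowers correlation but leaves the OLS
        slope unbiased, so a slope contrast needs saturating translation,
        which the generator does not model.)"""
        sim = simulate_cells(SimConfig(n_cells=1200, seed=21))
        rn, an = lognorm(sim.rna), clr_normalize(sim.adt, sim.sample_of)
        _, table = gene_level_concordance(rn, an, sim.ann)
        per_gene = per_gene_cell_correlation(rn, an, sim.ann)
        cyt = [r.rho for r in per_gene if r.defined and r.category == "cytokine"]
        non = [r.rho for r in per_gene if r.defined and r.category != "cytokine"]
        assert np.mean(cyt) < np.mean(non)
        regs = {r.class_label: r for r in class_regression(table)}
        assert regs["cytokine"].rho < regs["non_cytokine"].rho
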