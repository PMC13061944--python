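import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytolag.io_qc import NormMatrix, ValidationError, clr_normalize, lognorm
from cytolag.pseudolag import (
    SmoothedCurve,
    compute_pseudotime,
    cross_correlation_lag,
    delta_peak,
    rna_protein_kinetics,
    smooth_curve,
)
from cytolag.simulate import SimConfig, simulate_cells


def chain_matrix(n_cells=5, spacing=1.0):
    """Cells equally spaced on a line in a 2-feature space."""
    pos = np.arange(n_cells) * spacing
    values = np.vstack([pos, pos])
    return NormMatrix(values, ["f1", "f2"], [f"c{i}" for i in range(n_cells)], "lognorm_cp10k")


def chain_meta(n_cells=5, n_unstim=1):
    cond = ["unstimulated"] * n_unstim + ["stimulated"] * (n_cells - n_unstim)
    return pd.DataFrame(
        {"sample_id": "S1", "condition": cond, "cell_type": "T"},
        index=[f"c{i}" for i in range(n_cells)],
    )


class TestComputePseudotime:
    def test_chain_graph_exact(self):
        result = compute_pseudotime(chain_matrix(), chain_meta(), k=2, n_pcs=2)
        np.testing.assert_allclose(result.t.to_numpy(), [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)
        assert result.root_cell == "c0"
        assert result.unreachable_cells == []

    def test_duplicated_cells_preserve_ordering(self):
        base = chain_matrix()
        dup = NormMatrix(
            np.hstack([base.values, base.values]),
            base.feature_ids,
            [f"c{i}" for i in range(10)],
            "lognorm_cp10k",
        )
        meta = chain_meta(10, n_unstim=2)
        # duplicates share positions 0..4: cells 0..4 and 5..9
        meta.index = [f"c{i}" for i in range(10)]
        result = compute_pseudotime(dup, meta, k=3, n_pcs=2)
        t = result.t.to_numpy()
        order_first = np.argsort(t[:5])
        order_second = np.argsort(t[5:])
        np.testing.assert_array_equal(order_first, order_second)

    def test_k_too_small_errors(self):
        with pytest.raises(ValidationError):
            compute_pseudotime(chain_matrix(), chain_meta(), k=1)

    def test_single_condition_errors(self):
        meta = chain_meta(5, n_unstim=0)
        with pytest.raises(ValidationError):
            compute_pseudotime(chain_matrix(), meta, k=2)

    def test_recovers_latent_time_on_synthetic_data(self, default_sim):
        rn = lognorm(default_sim.rna)
        result = compute_pseudotime(rn, default_sim.meta)
        rho = stats.spearmanr(
            result.t.to_numpy(), default_sim.meta["true_pseudotime"].to_numpy()
        ).statistic
        assert rho >= 0.9
        assert result.t.min() == 0.0
        assert result.t.max() == 1.0


class TestSmoothCurve:
    def test_constant_signal(self):
        rng = np.random.default_rng(0)
        t = rng.random(50)
        curve = smooth_curve(t, np.full(50, 3.0))
        np.testing.assert_allclose(curve.values, 3.0)

    def test_identity_bias_below_bandwidth(self):
        t = np.linspace(0, 1, 2000)
        curve = smooth_curve(t, t, n_grid=101, bandwidth=0.05)
        interior = (curve.grid > 0.1) & (curve.grid < 0.9)
        assert np.max(np.abs(curve.values[interior] - curve.grid[interior])) < 0.05

    def test_linearity(self):
        rng = np.random.default_rng(1)
        t = rng.random(200)
        y = rng.normal(size=200)
        c1 = smooth_curve(t, 2.0 * y + 3.0)
        c2 = smooth_curve(t, y)
        np.testing.assert_allclose(c1.values, 2.0 * c2.values + 3.0, atol=1e-9)

    def test_smaller_bandwidth_tracks_step_better(self):
        t = np.linspace(0, 1, 4000)
        y = (t > 0.5).astype(float)
        err = {}
        for h in (0.1, 0.05):
            curve = smooth_curve(t, y, n_grid=101, bandwidth=h)
            err[h] = np.abs(curve.values - (curve.grid > 0.5)).mean()
        assert err[0.05] < err[0.1]

    def test_too_few_cells(self):
        with pytest.raises(ValidationError):
            smooth_curve([0.1] * 5, [1.0] * 5)


def shifted_curves(shift_steps, n_grid=101):
    grid = np.linspace(0, 1, n_grid)
    base = 1.0 / (1.0 + np.exp(-(grid - 0.45) / 0.07))
    shifted = np.roll(base, shift_steps)
    if shift_steps > 0:
        shifted[:shift_steps] = base[0]
    elif shift_steps < 0:
        shifted[shift_steps:] = base[-1]
    rna = SmoothedCurve(grid, base, 0.05, np.ones(n_grid))
    prot = SmoothedCurve(grid, shifted, 0.05, np.ones(n_grid))
    return rna, prot


class TestDeltaPeak:
    def test_identical_curves_zero(self):
        rna, _ = shifted_curves(0)
        assert delta_peak(rna, rna) == 0.0

    def test_constructed_shift(self):
        rna, prot = shifted_curves(5)
        assert delta_peak(rna, prot) == pytest.approx(0.05)

    def test_antisymmetric_construction(self):
        prot, rna = shifted_curves(5)  # RNA is the one shifted right
        assert delta_peak(rna, prot) == pytest.approx(-0.05)

    def test_flat_curve_undefined(self):
        grid = np.linspace(0, 1, 101)
        flat = SmoothedCurve(grid, np.ones(101), 0.05, np.ones(101))
        rna, _ = shifted_curves(0)
        assert np.isnan(delta_peak(rna, flat))


class TestCrossCorrelationLag:
    def test_identical_curves(self):
        rna, _ = shifted_curves(0)
        res = cross_correlation_lag(rna, rna)
        assert res.lag_max_corr == 0.0
        assert res.max_corr == pytest.approx(1.0)

    def test_planted_integer_shift(self):
        rna, prot = shifted_curves(5)
        res = cross_correlation_lag(rna, prot)
        assert res.lag_max_corr == pytest.approx(0.05, abs=0.02)

    def test_swap_negates_lag(self):
        rna, prot = shifted_curves(5)
        fwd = cross_correlation_lag(rna, prot)
        rev = cross_correlation_lag(prot, rna)
        assert rev.lag_max_corr == pytest.approx(-fwd.lag_max_corr)

    def test_lag_bound_respected(self):
        rna, prot = shifted_curves(5)
        res = cross_correlation_lag(rna, prot, max_lag_steps=10)
        assert abs(res.lag_max_corr) <= 10 * res.grid_spacing + 1e-12
        assert len(res.corr_at_lags) == 21

    def test_excessive_lag_window_rejected(self):
        rna, prot = shifted_curves(0)
        with pytest.raises(ValidationError):
            cross_correlation_lag(rna, prot, max_lag_steps=60)


class TestKinetics:
    def test_planted_lag_recovered_with_true_pseudotime(self, default_sim):
        sim = default_sim
        rn, an = lognorm(sim.rna), clr_normalize(sim.adt, sim.sample_of)
        # pick a lagged gene whose activation sits in the trajectory interior:
        # a rise too close to t = 1 is only partially observed and its lag
        # is not reliably estimable from the curves
        interior = (sim.truth.lag >= 0.04) & (sim.truth.midpoint > 0.3) & (sim.truth.midpoint < 0.6)
        idx = int(np.flatnonzero(interior)[0])
        gene = sim.truth.gene_ids[idx]
        lam = sim.truth.lag[idx]
        lag, rna_curve, prot_curve, _ = rna_protein_kinetics(
            rn, an, sim.meta, gene, pseudotime=sim.meta["true_pseudotime"]
        )
        assert lag.lag_max_corr == pytest.approx(lam, abs=0.03)
        assert lag.delta_peak > 0

    def test_determinism(self, default_sim):
        sim = default_sim
        rn, an = lognorm(sim.rna), clr_normalize(sim.adt, sim.sample_of)
        a = rna_protein_kinetics(rn, an, sim.meta, "IFNG", pseudotime=sim.meta["true_pseudotime"])
        b = rna_protein_kinetics(rn, an, sim.meta, "IFNG", pseudotime=sim.meta["true_pseudotime"])
        assert a[0].lag_max_corr == b[0].lag_max_corr
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_unknown_gene_errors(self, default_sim):
        sim = default_sim
        rn, an = lognorm(sim.rna), clr_normalize(sim.adt, sim.sample_of)
        with pytest.raises(ValidationError):
            rna_protein_kinetics(rn, an, sim.meta, "NOT_A_GENE")
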