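"""Ground-truth generator: prevalence dynamics, dosage model, determinism."""

import numpy as np
import pandas as pd
import pytest

from clonewatch.simulate import (
    SimulationParams,
    _dosage_factor,
    expected_counts,
    simulate_cells,
    simulate_chip_counts,
    simulate_truth,
)


class TestPrevalenceDynamics:
    def test_equal_fitness_keeps_symmetric_prevalence(self):
        params = SimulationParams(
            n_bins=30, n_clones=2, n_passages=1, conditions=("UnRx",),
            fitness={"A": 1.0, "B": 1.0}, rx_fitness={"A": 1.0, "B": 1.0},
            initial_prevalence={"A": 0.5, "B": 0.5}, cells_per_sample=200, seed=0,
        )
        truth = simulate_truth(params)
        # the deterministic update preserves symmetry exactly
        assert truth.prevalence.loc["UnRx_X1"].tolist() == [0.5, 0.5]
        # counted labels agree within multinomial error (3 sigma)
        n_b = (truth.cell_truth["clone"] == "B").sum()
        assert abs(n_b - 100) < 3 * np.sqrt(200 * 0.25)

    def test_resistant_clone_sweeps_monotonically_under_treatment(self):
        params = SimulationParams(
            n_bins=30, n_clones=2, n_passages=4,
            fitness={"A": 1.0, "B": 1.0},
            rx_fitness={"A": 1.0, "B": 10.0},
            initial_prevalence={"A": 0.9, "B": 0.1},
            cells_per_sample=100, seed=1,
        )
        truth = simulate_truth(params)
        rx = truth.prevalence.loc[[f"Rx_X{x}" for x in range(1, 5)], "B"]
        assert (np.diff(rx) >= 0).all()
        # independent brute-force iteration of the selection update
        p = np.array([0.9, 0.1])
        expected = []
        for _ in range(4):
            p = p * np.array([1.0, 10.0])
            p /= p.sum()
            expected.append(p[1])
        np.testing.assert_allclose(rx.to_numpy(), expected, rtol=1e-12)

    def test_prevalence_rows_sum_to_one(self, small_truth):
        np.testing.assert_allclose(small_truth.prevalence.sum(1), 1.0, atol=1e-9)

    def test_label_counts_match_deterministic_prevalence(self, small_truth, small_params):
        n = small_params.cells_per_sample
        for sample, row in small_truth.prevalence.iterrows():
            cells = small_truth.cell_truth[small_truth.cell_truth["sample"] == sample]
            for clone, p in row.items():
                k = (cells["clone"] == clone).sum()
                # binomial 99 % CI around the deterministic prevalence
                half = 2.58 * np.sqrt(n * p * (1 - p)) + 1
                assert abs(k - n * p) <= half, (sample, clone)

    def test_clone_profiles_pairwise_distinct_and_bounded(self, small_truth):
        cn = small_truth.clone_cn.to_numpy()
        assert cn.min() >= 0 and cn.max() <= 8
        for i in range(cn.shape[0]):
            for j in range(i + 1, cn.shape[0]):
                assert (cn[i] != cn[j]).any()


class TestValidation:
    def test_single_clone_rejected(self):
        with pytest.raises(ValueError, match="clones"):
            simulate_truth(SimulationParams(n_clones=1))

    def test_all_zero_fitness_rejected(self):
        params = SimulationParams(n_clones=2, fitness={"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError, match="fitness"):
            simulate_truth(params)

    @pytest.mark.parametrize("field,value", [
        ("frac_anticorrelated", 1.5), ("frac_mouse_cells", -0.1), ("flip_rate", 2.0),
    ])
    def test_fractions_out_of_range_rejected(self, field, value):
        with pytest.raises(ValueError, match=field):
            simulate_truth(SimulationParams(**{field: value}))

    def test_zero_base_mean_rejected(self, small_truth):
        import copy as _copy
        broken = _copy.deepcopy(small_truth)
        broken.base_mean.iloc[0] = 0.0
        with pytest.raises(ValueError, match="base_mean"):
            simulate_cells(broken)


class TestDosageModel:
    def test_copy_four_doubles_copy_two_at_unit_exponent(self):
        assert _dosage_factor(np.array([4.0]), np.array([1.0]))[0] == pytest.approx(2.0)
        assert (
            _dosage_factor(np.array([4.0]), np.array([1.0]))[0]
            / _dosage_factor(np.array([2.0]), np.array([1.0]))[0]
        ) == pytest.approx(2.0)

    def test_zero_exponent_removes_copy_dependence(self):
        f = _dosage_factor(np.array([0.0, 1.0, 2.0, 4.0, 8.0]), np.zeros(5))
        np.testing.assert_allclose(f, 1.0)

    def test_anticorrelated_exponent_inverts_without_blowup(self):
        f = _dosage_factor(np.array([0.0, 1.0, 2.0, 4.0]), np.full(4, -1.0))
        np.testing.assert_allclose(f, [2.0, 2.0, 1.0, 0.5])

    def test_reversible_induction_mean_ratios(self):
        # planted induced_reversible gene, fold 2: Rx/UnRx ~ 2, RxH/UnRx ~ 1
        params = SimulationParams(
            n_bins=30, n_clones=2, genes_per_bin=5, n_passages=2,
            cells_per_sample=1000, frac_mouse_cells=0.0, frac_lowqc_cells=0.0,
            frac_anticorrelated=0.0, flip_rate=0.0,
            program_sizes={"induced_reversible": 20}, seed=3,
        )
        truth = simulate_truth(params)
        _, adata = simulate_cells(truth, params)
        # pick program genes in bins where both clones are diploid so the
        # clone mixture cannot contaminate the condition ratio
        genes = truth.genes
        flat = (truth.clone_cn.iloc[0] == 2) & (truth.clone_cn.iloc[1] == 2)
        picks = genes.index[
            (genes["program"] == "induced_reversible") & genes["bin"].map(flat)
        ]
        assert len(picks) >= 3
        conds = adata.obs["condition"].to_numpy()
        X = np.asarray(adata[:, picks].X, dtype=float)
        m = {c: X[conds == c].mean(0) for c in ("UnRx", "Rx", "RxH")}
        ratio_rx = np.mean(m["Rx"] / m["UnRx"])
        ratio_rxh = np.mean(m["RxH"] / m["UnRx"])
        assert ratio_rx == pytest.approx(2.0, rel=0.10)
        assert ratio_rxh == pytest.approx(1.0, rel=0.10)

    def test_empirical_means_match_generative_means(self):
        # >=5000 cells of one clone/condition: per-gene mean within 5 %
        # of the generative mean for mu >= 1
        params = SimulationParams(
            n_bins=30, n_clones=2, genes_per_bin=5, n_passages=1,
            conditions=("UnRx",), cells_per_sample=12000,
            frac_mouse_cells=0.0, frac_lowqc_cells=0.0, flip_rate=0.0,
            library_log_sigma=0.0, initial_prevalence={"A": 0.5, "B": 0.5}, seed=4,
        )
        truth = simulate_truth(params)
        _, adata = simulate_cells(truth, params)
        mask = (adata.obs["clone"] == "A").to_numpy()
        assert mask.sum() >= 5000
        X = np.asarray(adata[mask, truth.genes.index].X, dtype=float)
        expected = expected_counts(truth, "UnRx", "A").to_numpy()
        big = expected >= 1.0
        rel = np.abs(X.mean(0)[big] - expected[big]) / expected[big]
        assert np.quantile(rel, 0.95) < 0.05


class TestDeterminism:
    def test_same_seed_identical_truth_and_cells(self, small_params):
        t1 = simulate_truth(small_params)
        t2 = simulate_truth(small_params)
        pd.testing.assert_frame_equal(t1.clone_cn, t2.clone_cn)
        pd.testing.assert_frame_equal(t1.prevalence, t2.prevalence)
        pd.testing.assert_frame_equal(t1.cell_truth, t2.cell_truth)
        cn1, ad1 = simulate_cells(t1, small_params)
        cn2, ad2 = simulate_cells(t2, small_params)
        pd.testing.assert_frame_equal(cn1.copy, cn2.copy)
        np.testing.assert_array_equal(np.asarray(ad1.X), np.asarray(ad2.X))

    def test_same_seed_identical_chip_table(self, small_truth, small_params):
        t1 = simulate_chip_counts(small_truth, small_params)
        t2 = simulate_chip_counts(small_truth, small_params)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestChipCounts:
    def test_active_promoters_show_fivefold_k4_over_input(self, small_truth, small_params):
        table = simulate_chip_counts(small_truth, small_params)
        cls = table.counts["chromatin_class"]
        active = table.counts[cls == "active"]
        k4 = (active[["H3K4me3_1", "H3K4me3_2"]].to_numpy()
              / table.library_sizes[["H3K4me3_1", "H3K4me3_2"]].to_numpy()).mean()
        inp = (active[["input_1", "input_2"]].to_numpy()
               / table.library_sizes[["input_1", "input_2"]].to_numpy()).mean()
        assert k4 / inp == pytest.approx(5.0, rel=0.1)

    def test_control_block_matches_repressed_class_distribution(self, small_truth, small_params):
        table = simulate_chip_counts(small_truth, small_params)
        cls = table.counts["chromatin_class"]
        is_ctrl = table.counts.index.str.startswith("CTRL")
        ctrl = table.counts[is_ctrl]
        repressed = table.counts[(cls == "repressed") & ~is_ctrl]
        # same generative parameters: Poisson means agree per track
        for col in ("H3K4me3_1", "H3K27me3_1", "input_1"):
            a, b = ctrl[col].mean(), repressed[col].mean()
            assert a == pytest.approx(b, rel=0.15), col
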