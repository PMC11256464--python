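"""Dosage-model clone assignment: gene filters, EM behavior, recovery."""

import numpy as np
import pandas as pd
import pytest

from clonewatch.clone_assign import (
    AssignmentParams,
    CloneAssignEM,
    assign_clones,
    proportion_concordance,
    select_assignment_genes,
)
from clonewatch.clone_cn import CNMatrix, clone_median_profiles, map_genes_to_bins
from clonewatch.simulate import SimulationParams, simulate_cells, simulate_truth


def _toy_setup(copies_a, copies_b, n_cells_per_clone=10, impure_frac=0.0):
    """Two clones over len(copies) bins, one gene per bin."""
    n_bins = len(copies_a)
    bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(n_bins) * 500_000,
                         "end": (np.arange(n_bins) + 1) * 500_000})
    rows, clones = [], []
    rng = np.random.default_rng(0)
    for label, base in (("A", copies_a), ("B", copies_b)):
        for i in range(n_cells_per_clone):
            row = np.array(base)
            if impure_frac and rng.random() < impure_frac:
                row = row + 1
            rows.append(row)
            clones.append(label)
    copy = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
    copy.columns = range(n_bins)
    cn = CNMatrix(bins=bins, copy=copy, clone=pd.Series(clones, index=copy.index))
    genes = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_bins) * 500_000 + 1000,
         "end": np.arange(n_bins) * 500_000 + 11_000},
        index=[f"g{i}" for i in range(n_bins)],
    )
    gene_map = map_genes_to_bins(genes, bins)
    return cn, clone_median_profiles(cn), gene_map


class TestGeneSelection:
    def test_impure_gene_excluded_at_purity_threshold(self):
        # 55 % of clone A cells carry the modal CN -> below the 0.6 default
        cn, profiles, gmap = _toy_setup([2, 4, 5], [2, 2, 2], n_cells_per_clone=20)
        copy = cn.copy.to_numpy()
        copy[:9, 1] = 3  # 9/20 A cells deviate at bin 1 -> purity 0.55
        cn.copy = pd.DataFrame(copy, index=cn.copy.index, columns=cn.copy.columns)
        profiles = clone_median_profiles(cn)
        kept = select_assignment_genes(cn, profiles, gmap, AssignmentParams(cn_purity=0.6))
        assert "g1" not in kept
        assert "g2" in kept

    def test_uninformative_equal_cn_gene_excluded(self):
        cn, profiles, gmap = _toy_setup([2, 4], [2, 2])
        kept = select_assignment_genes(cn, profiles, gmap, AssignmentParams())
        assert kept == ["g1"]  # g0 is CN 2 in both clones

    def test_saturation_collapses_high_amplifications(self):
        # CN 7 vs 8 both clip to 6 -> uninformative after saturation
        cn, profiles, gmap = _toy_setup([7, 4], [8, 2])
        kept = select_assignment_genes(cn, profiles, gmap, AssignmentParams(max_cn=6))
        assert kept == ["g1"]

    def test_no_passing_genes_raises_with_advice(self):
        cn, profiles, gmap = _toy_setup([2, 2], [2, 2])
        with pytest.raises(ValueError, match="cn_purity"):
            select_assignment_genes(cn, profiles, gmap, AssignmentParams())

    def test_noiseless_synthetic_retains_all_differing_bins(self):
        params = SimulationParams(n_bins=40, n_clones=2, flip_rate=0.0,
                                  cells_per_sample=100, n_passages=2, seed=6)
        truth = simulate_truth(params)
        cn, _ = simulate_cells(truth, params)
        profiles = clone_median_profiles(cn)
        gmap = map_genes_to_bins(truth.genes[["chrom", "start", "end"]], truth.bins)
        kept = select_assignment_genes(cn, profiles, gmap, AssignmentParams())
        differing = truth.clone_cn.iloc[0] != truth.clone_cn.iloc[1]
        informative = truth.genes.index[
            truth.genes["bin"].map(differing)
            & truth.genes["bin"].map(
                (truth.clone_cn.clip(upper=6).iloc[0] != truth.clone_cn.clip(upper=6).iloc[1])
            )
        ]
        assert set(kept) == set(informative)


class TestCloneAssignEM:
    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(100, 30))
        cn = np.vstack([np.full(30, 2.0), rng.choice([1, 2, 3, 4], 30)])
        est = CloneAssignEM(random_state=0).fit(X, cn)
        assert (np.diff(est.log_likelihood_trace_) >= -1e-6).all()

    def test_identical_clones_give_prior_posteriors(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5.0, size=(50, 20))
        cn = np.vstack([np.full(20, 3.0), np.full(20, 3.0)])
        est = CloneAssignEM(random_state=0, n_restarts=1).fit(X, cn)
        np.testing.assert_allclose(
            est.responsibilities_,
            np.broadcast_to(est.priors_, est.responsibilities_.shape),
            atol=1e-8,
        )

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(5.0, size=(60, 25))
        cn = np.vstack([np.full(25, 2.0), rng.choice([1, 3, 4], 25)])
        est = CloneAssignEM(random_state=0).fit(X, cn)
        np.testing.assert_allclose(est.responsibilities_.sum(1), 1.0, atol=1e-8)

    def test_same_seed_identical_assignments(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(4.0, size=(80, 40))
        cn = np.vstack([np.full(40, 2.0), rng.choice([1, 2, 4], 40)])
        a = CloneAssignEM(random_state=7).fit(X, cn).labels_
        b = CloneAssignEM(random_state=7).fit(X, cn).labels_
        np.testing.assert_array_equal(a, b)

    def test_clone_label_permutation_permutes_outputs(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(4.0, size=(80, 40))
        cn = np.vstack([np.full(40, 2.0), rng.choice([1, 2, 4], 40),
                        rng.choice([2, 3, 5], 40)])
        est1 = CloneAssignEM(random_state=0).fit(X, cn, clone_labels=["A", "B", "C"])
        perm = [2, 0, 1]
        est2 = CloneAssignEM(random_state=0).fit(
            X, cn[perm], clone_labels=np.array(["A", "B", "C"])[perm])
        np.testing.assert_array_equal(est1.labels_, est2.labels_)
        np.testing.assert_allclose(est1.responsibilities_,
                                   est2.responsibilities_[:, np.argsort(perm)],
                                   atol=1e-8)

    def test_single_clone_trivial_assignment(self):
        X = np.ones((10, 5))
        est = CloneAssignEM().fit(X, np.full((1, 5), 2.0), clone_labels=["A"])
        assert (est.predict() == "A").all()
        np.testing.assert_allclose(est.responsibilities_, 1.0)

    def test_empty_gene_list_raises(self):
        with pytest.raises(ValueError, match="empty gene list"):
            CloneAssignEM().fit(np.ones((5, 0)), np.ones((2, 0)))


@pytest.fixture(scope="module")
def recovered():
    params = SimulationParams(
        n_bins=60, n_clones=3, cells_per_sample=300, n_passages=3,
        frac_mouse_cells=0.0, frac_lowqc_cells=0.0, seed=8,
    )
    truth = simulate_truth(params)
    cn, adata = simulate_cells(truth, params)
    profiles = clone_median_profiles(cn)
    gmap = map_genes_to_bins(truth.genes[["chrom", "start", "end"]], truth.bins)
    ap = AssignmentParams(seed=8)
    genes = select_assignment_genes(cn, profiles, gmap, ap)
    human = adata[:, list(truth.genes.index)]
    result = assign_clones(human, profiles, genes, ap, gmap)
    return truth, cn, result


class TestAssignmentRecovery:
    def test_accuracy_at_least_ninety_percent(self, recovered):
        truth, _, result = recovered
        true_clone = truth.cell_truth["clone"].reindex(result.assignments.index)
        assert (result.assignments == true_clone).mean() >= 0.90

    def test_proportion_concordance_high(self, recovered):
        truth, cn, result = recovered
        table, r = proportion_concordance(result, cn, truth.cell_truth["sample"])
        assert r >= 0.95
        sums = table.groupby("sample")[["proportion_rna", "proportion_cn"]].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_low_count_cells_dropped_and_reported(self, recovered):
        truth, cn, result = recovered
        assert set(result.dropped_cells).isdisjoint(set(result.assignments.index))

    def test_perfect_assignment_gives_unit_correlation(self, recovered):
        truth, cn, _ = recovered
        # feed the CN truth itself on both sides
        from clonewatch.clone_assign import CloneAssignment
        fake = CloneAssignment(
            assignments=cn.clone.copy(),
            posterior=pd.get_dummies(cn.clone).astype(float),
            genes_used=[], log_likelihood_trace=np.array([0.0]),
        )
        _, r = proportion_concordance(fake, cn, truth.cell_truth["sample"])
        assert r == pytest.approx(1.0, abs=1e-12)
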