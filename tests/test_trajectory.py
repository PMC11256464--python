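"""Lineage inference, pseudotime recovery, gene tests, gene modules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau
from sklearn.metrics import adjusted_rand_score

from clonewatch.clone_cn import CloneProfileSet, GeneBinMap
from clonewatch.simulate import (
    simulate_branching_trajectory,
    simulate_linear_trajectory,
)
from clonewatch.trajectory import (
    LineagePseudotime,
    annotate_lineage_cis_trans,
    cluster_gene_modules,
    lineage_gene_tests,
    normalize_counts,
    smoothed_lineage_curves,
)


@pytest.fixture(scope="module")
def linear_fit():
    adata, t = simulate_linear_trajectory(seed=0)
    est = LineagePseudotime(n_clusters=6, random_state=0).fit(adata)
    return adata, t, est


@pytest.fixture(scope="module")
def branch_fit():
    adata, t, branch = simulate_branching_trajectory(seed=0)
    est = LineagePseudotime(n_clusters=6, random_state=0).fit(adata)
    return adata, t, branch, est


def _primary_pseudotime(lin):
    w = lin.weights.to_numpy()
    pt = lin.pseudotime.to_numpy()
    prim = w.argmax(1)
    return np.array([pt[i, prim[i]] for i in range(len(prim))])


class TestLineageInference:
    def test_linear_data_yields_single_lineage(self, linear_fit):
        _, _, est = linear_fit
        assert est.lineage_set_.n_lineages == 1

    def test_pseudotime_tracks_latent_time(self, linear_fit):
        _, t, est = linear_fit
        pt = _primary_pseudotime(est.lineage_set_)
        ok = ~np.isnan(pt)
        assert kendalltau(pt[ok], t[ok]).statistic >= 0.8

    def test_pseudotime_in_unit_interval(self, linear_fit):
        _, _, est = linear_fit
        pt = est.lineage_set_.pseudotime.to_numpy()
        finite = pt[np.isfinite(pt)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0

    def test_cluster_mean_pseudotime_monotone_along_path(self, linear_fit):
        _, _, est = linear_fit
        lin = est.lineage_set_
        path = lin.lineages[0]
        pt = lin.pseudotime.iloc[:, 0]
        means = [pt[est.clusters_ == c].mean() for c in path]
        assert (np.diff(means) > 0).all()

    def test_branching_data_yields_shared_trunk(self, branch_fit):
        _, _, _, est = branch_fit
        lin = est.lineage_set_
        assert lin.n_lineages >= 2
        shared = set(lin.lineages[0]) & set(lin.lineages[1])
        assert len(shared) >= 1
        assert lin.lineages[0][0] == lin.lineages[1][0] == lin.start_cluster

    def test_weights_rows_sum_to_one_for_on_lineage_cells(self, branch_fit):
        _, _, _, est = branch_fit
        w = est.lineage_set_.weights.to_numpy()
        on = w.sum(1) > 0
        np.testing.assert_allclose(w[on].sum(1), 1.0, atol=1e-9)

    def test_identical_cells_rejected(self):
        from anndata import AnnData
        X = np.ones((100, 20))
        obs = pd.DataFrame({"condition": ["UnRx"] * 100, "passage": [1] * 100},
                           index=[f"c{i}" for i in range(100)])
        adata = AnnData(X=X, obs=obs)
        with pytest.raises(ValueError, match="degenerate|identical"):
            LineagePseudotime(n_clusters=4, random_state=0).fit(adata)

    def test_start_rule_prefers_untreated_earliest_cells(self, linear_fit):
        adata, t, est = linear_fit
        start_cells = est.clusters_ == est.start_cluster_
        assert t[start_cells.to_numpy()].mean() < 0.3


class TestNormalization:
    def test_silent_genes_dropped(self):
        from anndata import AnnData
        rng = np.random.default_rng(0)
        X = rng.poisson(3, (100, 10)).astype(float)
        X[:98, 0] = 0  # zero in 98 % of cells: beyond the 97.5 % cutoff
        adata = AnnData(X=X, var=pd.DataFrame(index=[f"g{i}" for i in range(10)]))
        out = normalize_counts(adata)
        assert "g0" not in out.var_names and out.n_vars == 9

    def test_monotone_in_counts(self):
        from anndata import AnnData
        X = np.array([[1.0, 5.0, 10.0], [1.0, 5.0, 10.0]])
        adata = AnnData(X=X, var=pd.DataFrame(index=["a", "b", "c"]))
        out = normalize_counts(adata)
        row = np.asarray(out.X)[0]
        assert row[0] < row[1] < row[2]


@pytest.fixture(scope="module")
def tested(branch_fit):
    adata, _, _, est = branch_fit
    norm = normalize_counts(adata)
    return lineage_gene_tests(norm, est.lineage_set_, n_perm=200, seed=0)


class TestLineageGeneTests:
    def test_trunk_genes_not_pattern_significant(self, tested):
        trunk = tested.iloc[:20]
        assert (trunk["pattern_p_adj"] < 0.05).mean() <= 0.1

    def test_late_diverging_genes_end_significant_not_early(self, tested):
        branch_genes = tested.iloc[20:60]
        assert (branch_genes["end_p"] < 0.05).mean() >= 0.8
        assert (branch_genes["early_p"] < 0.05).mean() <= 0.2

    def test_permuted_lineage_labels_destroy_signal(self, branch_fit):
        adata, _, _, est = branch_fit
        lin = est.lineage_set_
        rng = np.random.default_rng(1)
        shuffled = lin.weights.copy()
        perm = rng.permutation(len(shuffled))
        shuffled.iloc[:] = shuffled.to_numpy()[perm]
        pt = lin.pseudotime.copy()
        pt.iloc[:] = pt.to_numpy()[perm]
        from clonewatch.trajectory import LineageSet
        broken = LineageSet(clusters=lin.clusters, mst_edges=lin.mst_edges,
                            lineages=lin.lineages, pseudotime=pt, weights=shuffled,
                            start_cluster=lin.start_cluster)
        norm = normalize_counts(adata)
        tests = lineage_gene_tests(norm, broken, n_perm=100, seed=0)
        assert tests["pattern_p"].iloc[20:60].median() > 0.3

    def test_single_usable_lineage_rejected(self, linear_fit):
        adata, _, est = linear_fit
        norm = normalize_counts(adata)
        with pytest.raises(ValueError, match="lineages"):
            lineage_gene_tests(norm, est.lineage_set_, n_perm=10, seed=0)


@pytest.fixture(scope="module")
def branch_curves(branch_fit):
    adata, _, _, est = branch_fit
    norm = normalize_counts(adata)
    genes = [g for g in norm.var_names if g >= "B020"]  # two archetypes
    return smoothed_lineage_curves(norm, est.lineage_set_, genes), genes


class TestGeneModules:
    def test_two_archetypes_recovered(self, branch_curves):
        curves, genes = branch_curves
        modules = cluster_gene_modules(curves, seed=0)
        truth = [0 if g < "B040" else 1 for g in genes]
        ari = adjusted_rand_score(truth, modules.labels.loc[genes])
        assert ari >= 0.9

    def test_duplicate_genes_share_a_module(self, branch_curves):
        curves, genes = branch_curves
        dup = {ln: pd.concat([c, c.iloc[[0]].rename(index={c.index[0]: "dup"})])
               for ln, c in curves.items()}
        modules = cluster_gene_modules(dup, seed=0)
        assert modules.labels["dup"] == modules.labels[curves["L1"].index[0]]

    def test_same_seed_same_modules(self, branch_curves):
        curves, _ = branch_curves
        m1 = cluster_gene_modules(curves, seed=0)
        m2 = cluster_gene_modules(curves, seed=0)
        pd.testing.assert_series_equal(m1.labels, m2.labels)

    def test_module_curves_bounded_by_two(self, branch_curves):
        curves, _ = branch_curves
        modules = cluster_gene_modules(curves, seed=0)
        assert np.abs(modules.curves.to_numpy()).max() <= 2.0 + 1e-12

    def test_flat_curve_gene_dropped_with_warning(self, branch_curves):
        curves, _ = branch_curves
        flat = {ln: pd.concat([
            c, pd.DataFrame(np.zeros((1, c.shape[1])), index=["flat"])])
            for ln, c in curves.items()}
        with pytest.warns(UserWarning, match="flat"):
            modules = cluster_gene_modules(flat, seed=0)
        assert modules.labels["flat"] == -1

    def test_too_few_genes_rejected(self):
        curves = {"L1": pd.DataFrame(np.ones((3, 10)), index=["a", "b", "c"])}
        with pytest.raises(ValueError, match=">=10"):
            cluster_gene_modules(curves, seed=0)


class TestLineageCisTrans:
    def _lineage(self, cells, lineage_names=("L1",)):
        pt = pd.DataFrame({ln: np.linspace(0, 1, len(cells)) for ln in lineage_names},
                          index=cells)
        w = pd.DataFrame({ln: 1.0 / len(lineage_names) for ln in lineage_names},
                         index=cells)
        from clonewatch.trajectory import LineageSet
        return LineageSet(clusters=pd.Series(0, index=cells), mst_edges=[],
                          lineages=[[0]] * len(lineage_names), pseudotime=pt,
                          weights=w)

    def _profiles_and_map(self):
        bins = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100],
                             "end": [100, 200]})
        profiles = CloneProfileSet(
            bins=bins,
            median_cn=pd.DataFrame([[2.0, 4.0], [2.0, 2.0]], index=["A", "B"]))
        table = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 100], "end": [100, 200],
             "bin": [0, 1], "overlap_bp": 100, "spans_boundary": False},
            index=["g0", "g1"])
        return profiles, GeneBinMap(table=table)

    def test_single_clone_lineage_all_in_trans(self):
        cells = [f"c{i}" for i in range(40)]
        lin = self._lineage(cells)
        clones = pd.Series("A", index=cells)
        profiles, gmap = self._profiles_and_map()
        with pytest.warns(UserWarning, match="single clone"):
            flags = annotate_lineage_cis_trans(["g0", "g1"], lin, clones,
                                               profiles, gmap)
        assert not flags.to_numpy().any()

    def test_differing_bin_flagged_in_cis(self):
        cells = [f"c{i}" for i in range(40)]
        lin = self._lineage(cells)
        clones = pd.Series(["A", "B"] * 20, index=cells)
        profiles, gmap = self._profiles_and_map()
        flags = annotate_lineage_cis_trans(["g0", "g1"], lin, clones,
                                           profiles, gmap)
        assert not flags.loc["g0", "L1"]  # CN 2 vs 2
        assert flags.loc["g1", "L1"]  # CN 4 vs 2

    def test_rare_clone_below_threshold_ignored(self):
        cells = [f"c{i}" for i in range(100)]
        lin = self._lineage(cells)
        clones = pd.Series(["A"] * 98 + ["B"] * 2, index=cells)  # B at 2 %
        profiles, gmap = self._profiles_and_map()
        with pytest.warns(UserWarning, match="single clone"):
            flags = annotate_lineage_cis_trans(["g1"], lin, clones,
                                               profiles, gmap)
        assert not flags.loc["g1", "L1"]
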