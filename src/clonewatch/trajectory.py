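"""Lineage inference, pseudotime, lineage-aware gene tests, gene modules.

A deliberately transparent trajectory stage: cells are log-normalized,
reduced to principal components over highly variable genes, k-means
clustered, and a minimum spanning tree over cluster centroids defines
the global lineage structure.  Lineages are root-to-leaf paths from a
start cluster (the one richest in untreated cells from the earliest
passage); per-cell pseudotime is the normalized arc-length of the cell's
orthogonal projection onto its lineage's piecewise-linear centroid path.
Principal curves are intentionally not fitted — the piecewise-linear
path is deterministic and sufficient for monotone pseudotime recovery.

Gene-level lineage tests replace parametric GAM Wald tests with
permutation statistics on smoothed mean curves over a common pseudotime
grid: a pattern statistic (integrated squared curve difference), plus
end/early statistics (smoothed-mean differences in the last/first
pseudotime decile), with a null built by shuffling lineage labels within
pseudotime bins.

Significant genes are grouped into regulatory modules by cosine distance
between their concatenated per-lineage curves, embedded by PCA and
clustered with Leiden on a kNN graph (agglomerative average linkage when
igraph/leidenalg are unavailable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


from .dge import benjamini_hochberg, size_factors

__all__ = [
    "LineageSet",
    "GeneModuleSet",
    "normalize_counts",
    "LineagePseudotime",
    "infer_lineages",
    "lineage_gene_tests",
    "GeneModuleClustering",
    "cluster_gene_modules",
    "smoothed_lineage_curves",
    "annotate_lineage_cis_trans",
]

GRID_SIZE = 100
ZERO_FRAC_CUTOFF = 0.975  # drop genes with zero counts in > 97.5 % of cells


@dataclass
class LineageSet:
    clusters: pd.Series  # cell -> cluster id (-1 = removed outlier cluster)
    mst_edges: list  # (cluster, cluster) pairs
    lineages: list  # ordered cluster paths, each starting at start_cluster
    pseudotime: pd.DataFrame  # cells x lineages, NaN off-lineage, in [0, 1]
    weights: pd.DataFrame  # cells x lineages, rows sum to 1 over on-lineage entries
    start_cluster: int = 0

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def cells_on(self, lineage: int, min_weight: float = 0.0) -> pd.Index:
        w = self.weights.iloc[:, lineage]
        t = self.pseudotime.iloc[:, lineage]
        return self.weights.index[(w > min_weight) & t.notna()]


@dataclass
class GeneModuleSet:
    modules: dict  # module id -> gene list
    curves: pd.DataFrame  # (module, lineage) x grid, scaled to [-2, 2]
    labels: pd.Series  # gene -> module id
    chromatin_status: dict = field(default_factory=dict)


def normalize_counts(adata: AnnData, *, zero_frac: float = ZERO_FRAC_CUTOFF,
                     drop_mito: bool = True) -> AnnData:
    """Size-factor log normalization: log1p(count / sf), after dropping
    genes with zero counts in more than ``zero_frac`` of cells and
    (optionally) mitochondrial confounders."""
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    X = X.astype(float)
    keep = (X > 0).mean(0) >= (1.0 - zero_frac)
    if drop_mito:
        keep &= ~adata.var_names.str.contains(r"^MT-", regex=True)
    sf = size_factors(X)
    out = adata[:, keep].copy()
    out.X = np.log1p(X[:, keep] / sf[:, None])
    out.layers["counts"] = X[:, keep]
    return out


def _hvg_mask(X: np.ndarray, n_hvg: int) -> np.ndarray:
    """Top genes by standardized variance of the log-normalized matrix."""
    mean = X.mean(0)
    var = X.var(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        std_var = np.where(mean > 0, var / (mean + 1e-8), 0.0)
    k = min(n_hvg, X.shape[1])
    cutoff = np.partition(std_var, -k)[-k]
    mask = std_var >= cutoff
    return mask


class LineagePseudotime(BaseEstimator):
    """MST-over-centroids lineage and pseudotime estimator.

    Parameters
    ----------
    n_hvg : number of highly variable genes kept (3000 by default).
    n_pcs : principal components for the embedding (30).
    n_clusters : k for k-means (8) — the resolution analogue.
    min_cluster_frac : clusters smaller than this fraction of cells are
        treated as outliers and removed before lineage inference.
    start_rule : "untreated_earliest" picks the cluster with the most
        untreated cells from the earliest passage; "largest" the biggest
        cluster.

    After ``fit`` the result is available as ``lineage_set_`` plus the
    individual fitted attributes.
    """

    def __init__(self, n_hvg: int = 3000, n_pcs: int = 30, n_clusters: int = 8,
                 min_cluster_frac: float = 0.01, start_rule: str = "untreated_earliest",
                 random_state: int = 0, normalize: bool = True):
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.n_clusters = n_clusters
        self.min_cluster_frac = min_cluster_frac
        self.start_rule = start_rule
        self.random_state = random_state
        self.normalize = normalize

    def fit(self, adata: AnnData):
        norm = normalize_counts(adata) if self.normalize else adata
        X = norm.X.toarray() if hasattr(norm.X, "toarray") else np.asarray(norm.X)
        if X.shape[0] < 2 * self.n_clusters:
            raise ValueError("too few cells for the requested cluster count")
        mask = _hvg_mask(X, self.n_hvg)
        Xh = X[:, mask]
        if np.allclose(Xh.std(0).sum(), 0):
            raise ValueError("degenerate input: all cells identical")
        n_pcs = min(self.n_pcs, Xh.shape[1] - 1, Xh.shape[0] - 1)
        pca = PCA(n_components=n_pcs, random_state=self.random_state)
        Z = pca.fit_transform(Xh)

        km = KMeans(n_clusters=self.n_clusters, n_init=10, random_state=self.random_state)
        labels = km.fit_predict(Z)
        # remove small outlier clusters before lineage inference
        counts = np.bincount(labels, minlength=self.n_clusters)
        small = counts < self.min_cluster_frac * len(labels)
        labels = np.where(small[labels], -1, labels)
        keep_clusters = sorted(set(labels) - {-1})
        if len(keep_clusters) < 2:
            raise ValueError("fewer than 2 clusters after outlier removal")
        centroids = {c: Z[labels == c].mean(0) for c in keep_clusters}

        g = nx.Graph()
        for i, a in enumerate(keep_clusters):
            for b in keep_clusters[i + 1:]:
                g.add_edge(a, b, weight=float(np.linalg.norm(centroids[a] - centroids[b])))
        mst = nx.minimum_spanning_tree(g)

        start = self._pick_start(adata, labels, keep_clusters)
        leaves = [c for c in mst.nodes if mst.degree[c] == 1 and c != start]
        if not leaves:  # start is the only leaf of a path graph
            leaves = [c for c in mst.nodes if c != start and mst.degree[c] == 1]
        lineages = [nx.shortest_path(mst, start, leaf) for leaf in sorted(leaves)]
        if not lineages:
            raise ValueError("no lineages could be traced from the start cluster")

        pt, wt = self._project(Z, labels, centroids, lineages, adata.obs_names)

        self.pca_ = pca
        self.embedding_ = Z
        self.hvg_mask_ = mask
        self.clusters_ = pd.Series(labels, index=adata.obs_names, name="cluster")
        self.centroids_ = centroids
        self.mst_edges_ = sorted(tuple(sorted(e)) for e in mst.edges)
        self.start_cluster_ = start
        self.lineages_ = lineages
        self.pseudotime_ = pt
        self.weights_ = wt
        self.lineage_set_ = LineageSet(
            clusters=self.clusters_, mst_edges=self.mst_edges_, lineages=lineages,
            pseudotime=pt, weights=wt, start_cluster=start,
        )
        return self

    def fit_predict(self, adata: AnnData) -> LineageSet:
        return self.fit(adata).lineage_set_

    def _pick_start(self, adata, labels, clusters) -> int:
        if self.start_rule == "largest":
            return int(max(clusters, key=lambda c: (labels == c).sum()))
        obs = adata.obs
        if "condition" not in obs or "passage" not in obs:
            raise ValueError("start rule needs obs columns 'condition' and 'passage'")
        untreated = obs["condition"].to_numpy() == "UnRx"
        if untreated.any():
            earliest = obs.loc[untreated, "passage"].min()
            pool = untreated & (obs["passage"].to_numpy() == earliest)
        else:
            earliest = obs["passage"].min()
            pool = obs["passage"].to_numpy() == earliest
        best, best_n = None, -1
        for c in clusters:
            n = int((pool & (labels == c)).sum())
            if n > best_n:
                best, best_n = c, n
        if best_n == 0:
            best = int(max(clusters, key=lambda c: (labels == c).sum()))
        if best is None:
            raise ValueError("start rule selected an empty cluster")
        return int(best)

    def _project(self, Z, labels, centroids, lineages, index):
        n = Z.shape[0]
        L = len(lineages)
        pt = np.full((n, L), np.nan)
        dist = np.full((n, L), np.inf)
        on = np.zeros((n, L), dtype=bool)
        # one shared scale across lineages so trunk cells land at the same
        # pseudotime whichever lineage they are read on
        totals = []
        for path in lineages:
            pts = np.array([centroids[c] for c in path])
            totals.append(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        global_total = max(max(totals), 1e-12)
        for li, path in enumerate(lineages):
            pts = np.array([centroids[c] for c in path])
            seg = np.diff(pts, axis=0)
            seg_len = np.linalg.norm(seg, axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            total = global_total
            member = np.isin(labels, path)
            on[:, li] = member
            idx = np.where(member)[0]
            if len(idx) == 0:
                continue
            zc = Z[idx]
            best_t = np.full(len(idx), np.nan)
            best_d = np.full(len(idx), np.inf)
            for s in range(len(seg)):
                v = seg[s]
                denom = max(float(v @ v), 1e-12)
                tau = np.clip((zc - pts[s]) @ v / denom, 0.0, 1.0)
                proj = pts[s] + tau[:, None] * v
                d = np.linalg.norm(zc - proj, axis=1)
                arc = cum[s] + tau * seg_len[s]
                better = d < best_d
                best_d[better] = d[better]
                best_t[better] = arc[better]
            pt[idx, li] = best_t / total
            dist[idx, li] = best_d
        # weights: 1 for cells whose cluster lies on a single lineage,
        # split by inverse projection distance otherwise
        wt = np.zeros((n, L))
        for i in range(n):
            li = np.where(on[i])[0]
            if len(li) == 0:
                continue
            if len(li) == 1:
                wt[i, li[0]] = 1.0
            else:
                inv = 1.0 / (dist[i, li] + 1e-9)
                wt[i, li] = inv / inv.sum()
        cols = [f"L{j + 1}" for j in range(L)]
        return (
            pd.DataFrame(pt, index=index, columns=cols),
            pd.DataFrame(wt, index=index, columns=cols),
        )


def infer_lineages(adata: AnnData, *, n_hvg: int = 3000, n_pcs: int = 30,
                   n_clusters: int = 8, start_rule: str = "untreated_earliest",
                   random_state: int = 0) -> LineageSet:
    """Functional wrapper over :class:`LineagePseudotime`."""
    return LineagePseudotime(
        n_hvg=n_hvg, n_pcs=n_pcs, n_clusters=n_clusters,
        start_rule=start_rule, random_state=random_state,
    ).fit_predict(adata)


# ---------------------------------------------------------------------------
# smoothed per-lineage curves and permutation gene tests
# ---------------------------------------------------------------------------

def _primary_lineage(lin: LineageSet) -> np.ndarray:
    w = lin.weights.to_numpy()
    prim = np.where(w.sum(1) > 0, np.argmax(w, axis=1), -1)
    return prim


def _curve_matrix(expr: np.ndarray, t: np.ndarray, member: np.ndarray,
                  grid: np.ndarray, n_bins: int = 20, sigma: float = 1.0) -> np.ndarray:
    """Binned-mean curves, linearly interpolated onto the grid and
    lightly smoothed; genes x grid."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(t[member], edges) - 1, 0, n_bins - 1)
    sums = np.zeros((n_bins, expr.shape[1]))
    cnts = np.zeros(n_bins)
    np.add.at(sums, idx, expr[member])
    np.add.at(cnts, idx, 1.0)
    filled = cnts > 0
    centers = (edges[:-1] + edges[1:]) / 2
    means = sums[filled] / cnts[filled, None]
    out = np.empty((expr.shape[1], grid.size))
    for gi in range(expr.shape[1]):
        out[gi] = np.interp(grid, centers[filled], means[:, gi])
    return gaussian_filter1d(out, sigma=sigma, axis=1)


def smoothed_lineage_curves(adata: AnnData, lin: LineageSet, genes=None,
                            *, grid_size: int = GRID_SIZE) -> dict:
    """Per-lineage smoothed mean expression curves on a shared pseudotime
    grid.  Returns {lineage name: DataFrame genes x grid}."""
    if genes is None:
        genes = list(adata.var_names)
    sub = adata[:, genes]
    X = sub.X.toarray() if hasattr(sub.X, "toarray") else np.asarray(sub.X)
    grid = np.linspace(0.0, 1.0, grid_size)
    prim = _primary_lineage(lin)
    out = {}
    for li, col in enumerate(lin.pseudotime.columns):
        member = prim == li
        t = lin.pseudotime[col].to_numpy()
        member &= ~np.isnan(t)
        if member.sum() < 2:
            continue
        out[col] = pd.DataFrame(
            _curve_matrix(X, np.nan_to_num(t), member, grid), index=genes
        )
    return out


def lineage_gene_tests(adata: AnnData, lin: LineageSet, *, n_perm: int = 500,
                       seed: int = 0, min_cells: int = 20,
                       grid_size: int = GRID_SIZE) -> pd.DataFrame:
    """Permutation tests for between-lineage expression differences.

    Per gene three statistics on the smoothed per-lineage curves:

    * ``pattern_stat`` — integrated squared difference between lineage
      curves, summed over lineage pairs;
    * ``end_stat`` / ``early_stat`` — largest pairwise difference of the
      smoothed mean in the last / first pseudotime decile.

    The null shuffles lineage labels among cells within pseudotime bins,
    so pseudotime structure is preserved but lineage identity is not.
    Empirical p-values and BH adjustment per statistic.
    """
    prim = _primary_lineage(lin)
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    X = np.asarray(X, dtype=float)
    t_all = np.zeros(X.shape[0])
    for li, col in enumerate(lin.pseudotime.columns):
        m = prim == li
        t_all[m] = lin.pseudotime[col].to_numpy()[m]

    usable = []
    for li in range(lin.n_lineages):
        n = int((prim == li).sum())
        if n < min_cells:
            warnings.warn(f"lineage {li} has {n} cells (<{min_cells}); excluded")
        else:
            usable.append(li)
    if len(usable) < 2:
        raise ValueError("need >=2 lineages with enough cells")

    grid = np.linspace(0.0, 1.0, grid_size)
    early = grid <= 0.1
    late = grid >= 0.9

    def stats_for(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        curves = []
        for li in usable:
            member = (labels == li) & np.isfinite(t_all)
            curves.append(_curve_matrix(X, t_all, member, grid))
        pattern = np.zeros(X.shape[1])
        endd = np.zeros(X.shape[1])
        earlyd = np.zeros(X.shape[1])
        for i in range(len(curves)):
            for j in range(i + 1, len(curves)):
                diff = curves[i] - curves[j]
                pattern += (diff**2).mean(1)
                endd = np.maximum(endd, np.abs(diff[:, late].mean(1)))
                earlyd = np.maximum(earlyd, np.abs(diff[:, early].mean(1)))
        return pattern, endd, earlyd

    obs_pattern, obs_end, obs_early = stats_for(prim)

    rng = np.random.default_rng(seed)
    onlin = np.isin(prim, usable)
    bins = np.clip(np.digitize(t_all, np.linspace(0, 1, 11)) - 1, 0, 9)
    ge_p = np.zeros(X.shape[1])
    ge_e = np.zeros(X.shape[1])
    ge_a = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = prim.copy()
        for b in range(10):
            m = onlin & (bins == b)
            if m.sum() > 1:
                perm[m] = rng.permutation(prim[m])
        pp, pe, pa = stats_for(perm)
        ge_p += pp >= obs_pattern
        ge_e += pe >= obs_end
        ge_a += pa >= obs_early
    p_pattern = (ge_p + 1) / (n_perm + 1)
    p_end = (ge_e + 1) / (n_perm + 1)
    p_early = (ge_a + 1) / (n_perm + 1)

    return pd.DataFrame(
        {
            "pattern_stat": obs_pattern,
            "pattern_p": p_pattern,
            "pattern_p_adj": benjamini_hochberg(p_pattern),
            "end_stat": obs_end,
            "end_p": p_end,
            "end_p_adj": benjamini_hochberg(p_end),
            "early_stat": obs_early,
            "early_p": p_early,
            "early_p_adj": benjamini_hochberg(p_early),
        },
        index=adata.var_names,
    )


# ---------------------------------------------------------------------------
# gene-module clustering
# ---------------------------------------------------------------------------

class GeneModuleClustering(BaseEstimator, ClusterMixin):
    """Cosine-distance gene-module clustering of smoothed curves.

    Genes (rows) are described by their concatenated per-lineage curves;
    after PCA embedding (``n_components``), Leiden community detection
    on a cosine kNN graph assigns module labels.  When igraph/leidenalg
    are not installed, agglomerative clustering with average linkage on
    cosine distances is used with ``n_modules`` clusters.
    """

    def __init__(self, n_components: int = 25, n_neighbors: int = 15,
                 resolution: float = 0.1, n_modules: int | None = None,
                 random_state: int = 0):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.n_modules = n_modules
        self.random_state = random_state

    def fit(self, curves: pd.DataFrame):
        if len(curves) < 10:
            raise ValueError("need >=10 genes to cluster into modules")
        X = curves.to_numpy(dtype=float)
        X = X - X.mean(1, keepdims=True)  # relative expression: shape, not level
        norms = np.linalg.norm(X, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} flat/all-zero curve genes dropped "
                          "(cosine distance undefined)")
        keep = ~zero
        Xk = X[keep] / norms[keep, None]
        n_comp = min(self.n_components, Xk.shape[1], Xk.shape[0] - 1)
        Z = PCA(n_components=n_comp, random_state=self.random_state).fit_transform(Xk)
        labels_kept = self._cluster(Z)
        labels = np.full(len(curves), -1, dtype=int)
        labels[keep] = labels_kept
        self.labels_ = pd.Series(labels, index=curves.index, name="module")
        self.embedding_ = Z
        return self

    def _cluster(self, Z: np.ndarray) -> np.ndarray:
        try:
            import igraph
            import leidenalg
        except ImportError:
            igraph = None
        if igraph is not None and self.n_modules is None:
            n = Z.shape[0]
            k = min(self.n_neighbors, max(3, n // 5), n - 1)
            nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(Z)
            dist, nbrs = nn.kneighbors(Z)
            edges = {}
            for i in range(n):
                for d, j in zip(dist[i], nbrs[i]):
                    if i != int(j):
                        edges[tuple(sorted((i, int(j))))] = max(1.0 - d, 1e-6)
            keys = sorted(edges)
            g = igraph.Graph(n=n, edges=keys)
            part = leidenalg.find_partition(
                g, leidenalg.RBConfigurationVertexPartition,
                weights=[edges[e] for e in keys],
                resolution_parameter=self.resolution, seed=self.random_state,
            )
            return np.array(part.membership)
        n_modules = self.n_modules or 2
        agg = AgglomerativeClustering(
            n_clusters=n_modules, metric="cosine", linkage="average"
        )
        return agg.fit_predict(Z)

    def fit_predict(self, curves: pd.DataFrame, y=None) -> np.ndarray:
        self.fit(curves)
        return self.labels_.to_numpy()


def _scale_to_band(x: np.ndarray, lo: float = -2.0, hi: float = 2.0) -> np.ndarray:
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return np.zeros_like(x)
    return lo + (hi - lo) * (x - x.min()) / rng_


def cluster_gene_modules(curves_by_lineage: dict, *, n_components: int = 25,
                         resolution: float = 0.1, n_modules: int | None = None,
                         seed: int = 0) -> GeneModuleSet:
    """Cluster significant genes into modules from their smoothed curves.

    ``curves_by_lineage`` maps lineage name -> DataFrame (genes x grid),
    as produced by :func:`smoothed_lineage_curves`; the per-gene feature
    vector is the concatenation across lineages.  Module summary curves
    are per-module per-lineage means scaled to [-2, 2].
    """
    lineage_names = sorted(curves_by_lineage)
    concat = pd.concat([curves_by_lineage[n] for n in lineage_names], axis=1)
    est = GeneModuleClustering(
        n_components=n_components, resolution=resolution,
        n_modules=n_modules, random_state=seed,
    ).fit(concat)
    labels = est.labels_
    modules = {
        f"M{m + 1}": list(labels.index[labels == m])
        for m in sorted(labels[labels >= 0].unique())
    }
    rows = []
    idx = []
    for mod, genes in modules.items():
        for ln in lineage_names:
            mean_curve = curves_by_lineage[ln].loc[genes].mean(0).to_numpy()
            rows.append(_scale_to_band(mean_curve))
            idx.append((mod, ln))
    curves = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(idx, names=["module", "lineage"]))
    return GeneModuleSet(modules=modules, curves=curves, labels=labels)


def annotate_lineage_cis_trans(genes, lin: LineageSet, clone_of_cell: pd.Series,
                               profiles, gene_map, *, min_clone_frac: float = 0.05
                               ) -> pd.DataFrame:
    """Per-gene per-lineage in-cis flag.

    Within a lineage, collect the clones making up at least
    ``min_clone_frac`` of its cells; a gene is in-cis for that lineage
    iff the clone median copy number at its bin differs between any pair
    of those clones.  Single-clone lineages have no CN contrast: all
    genes in-trans there.
    """
    bins = gene_map.table.loc[list(genes), "bin"].to_numpy()
    out = {}
    for li, col in enumerate(lin.pseudotime.columns):
        cells = lin.cells_on(li)
        clones = clone_of_cell.reindex(cells).dropna()
        clones = clones[clones != "unassigned"]
        if len(clones) == 0:
            out[col] = np.zeros(len(genes), dtype=bool)
            continue
        freq = clones.value_counts(normalize=True)
        present = [c for c in freq.index if freq[c] >= min_clone_frac]
        if len(present) < 2:
            warnings.warn(f"lineage {col} carries a single clone; all genes in-trans")
            out[col] = np.zeros(len(genes), dtype=bool)
            continue
        med = profiles.median_cn.loc[present].to_numpy()
        differ = (med.max(0) - med.min(0)) > 0
        flags = np.zeros(len(genes), dtype=bool)
        ok = bins >= 0
        flags[ok] = differ[bins[ok]]
        out[col] = flags
    return pd.DataFrame(out, index=list(genes))
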