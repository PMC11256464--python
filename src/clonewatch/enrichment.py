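"""Preranked gene set enrichment with permutation-normalized scores.

Classic weighted Kolmogorov-Smirnov running-sum enrichment: genes are
ranked by a score (log2 fold change here), hits inside a set advance the
running sum in proportion to |score|^p (p = 1 by default), misses
retreat it by 1/(N - N_hit); the enrichment score ES is the extremum of
the running sum.  Significance comes from gene-label permutations: the
normalized score NES is ES divided by the mean |permuted ES| of the same
sign, and the empirical p-value is computed within the sign class.
BH adjustment is applied across sets.

Also provides the four-way pathway change categorization between a
treated and a holiday contrast, and reference-gene-set overlap reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import benjamini_hochberg

__all__ = [
    "GeneSetCollection",
    "enrichment_score",
    "preranked_gsea",
    "pathway_change_categories",
    "reference_set_overlap",
]

PATHWAY_CATEGORIES = ("Rx_only", "RxH_only", "both_same_direction",
                      "both_reverse_direction", "neither")


@dataclass
class GeneSetCollection:
    """Named gene sets with size bounds applied at access time."""

    sets: dict
    min_size: int = 5
    max_size: int = 500

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def within_bounds(self, universe=None) -> dict:
        out = {}
        for name, genes in self.sets.items():
            eff = [g for g in genes if universe is None or g in universe]
            if self.min_size <= len(eff) <= self.max_size:
                out[name] = eff
        return out

    def items(self):
        return self.sets.items()

    def __len__(self) -> int:
        return len(self.sets)


def _sorted_ranking(ranked: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Descending score order, ties broken by gene id for determinism."""
    order = np.lexsort((ranked.index.to_numpy(), -ranked.to_numpy(dtype=float)))
    return ranked.index.to_numpy()[order], ranked.to_numpy(dtype=float)[order]


def _es_from_hits(scores: np.ndarray, hit: np.ndarray, p: float) -> tuple[float, np.ndarray]:
    n = scores.size
    n_hit = int(hit.sum())
    w = np.abs(scores) ** p
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal weights
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    running = np.cumsum(hit_w / denom - np.where(hit, 0.0, 1.0 / (n - n_hit)))
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), running


def enrichment_score(ranked: pd.Series, gene_set, *, p: float = 1.0
                     ) -> tuple[float, np.ndarray, list]:
    """Weighted KS enrichment score for one set on one ranked list.

    ``ranked`` maps gene -> score; it is sorted descending internally,
    ties broken by gene id for determinism.  Returns (ES, running sum,
    leading-edge genes).
    """
    genes, scores = _sorted_ranking(ranked)
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == genes.size:
        raise ValueError("gene set shares no (or all) genes with the ranking")
    es, running = _es_from_hits(scores, hit, p)
    i_ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def preranked_gsea(ranked: pd.Series, sets: GeneSetCollection, *,
                   n_perm: int = 1000, p: float = 1.0, seed: int = 0
                   ) -> pd.DataFrame:
    """Run preranked GSEA over a collection; one row per retained set.

    Columns: es, nes, p_value, p_adj, direction (up iff NES > 0),
    n_genes, leading_edge.
    """
    ranked = ranked.astype(float)
    if not np.all(np.isfinite(ranked)):
        raise ValueError("ranked scores must be finite")
    rng = np.random.default_rng(seed)
    universe = set(ranked.index)
    usable = {}
    for name, genes in sets.items():
        eff = [g for g in genes if g in universe]
        if len(eff) == 0:
            warnings.warn(f"gene set {name!r} entirely absent from the ranking; skipped")
            continue
        if len(eff) == len(universe):
            warnings.warn(f"gene set {name!r} covers the whole ranking; skipped")
            continue
        if not (sets.min_size <= len(eff) <= sets.max_size):
            continue
        usable[name] = eff
    genes_sorted, scores_sorted = _sorted_ranking(ranked)
    n = genes_sorted.size
    rows = []
    for name, genes in usable.items():
        es, _, leading = enrichment_score(ranked, genes, p=p)
        k = len(genes)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=k, replace=False)] = True
            perm_es[b], _ = _es_from_hits(scores_sorted, hit, p)
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same) == 0:
            nes = np.nan
            pval = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same))
            pval = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
        rows.append((name, es, nes, pval, "up" if es > 0 else "down", k, ";".join(leading)))
    out = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p_value", "direction", "n_genes", "leading_edge"]
    ).set_index("set")
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_value"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def pathway_change_categories(rx_results: pd.DataFrame, rxh_results: pd.DataFrame,
                              *, alpha: float = 0.05) -> pd.DataFrame:
    """Four-way treated-versus-holiday pathway status.

    ``Rx_only``: enriched (p < alpha) on drug but not on holiday;
    ``RxH_only`` the reverse; ``both_same_direction`` / ``both_reverse_
    direction`` when enriched in both with matching / opposite NES sign;
    ``neither`` otherwise.
    """
    if set(rx_results.index) != set(rxh_results.index):
        raise ValueError("result tables cover different pathway collections")
    rxh = rxh_results.loc[rx_results.index]
    sig_rx = rx_results["p_value"] < alpha
    sig_rxh = rxh["p_value"] < alpha
    same = rx_results["direction"].to_numpy() == rxh["direction"].to_numpy()
    category = np.select(
        [
            sig_rx & ~sig_rxh,
            ~sig_rx & sig_rxh,
            sig_rx & sig_rxh & same,
            sig_rx & sig_rxh & ~same,
        ],
        ["Rx_only", "RxH_only", "both_same_direction", "both_reverse_direction"],
        default="neither",
    )
    return pd.DataFrame(
        {
            "category": pd.Categorical(category, categories=list(PATHWAY_CATEGORIES)),
            "p_rx": rx_results["p_value"],
            "dir_rx": rx_results["direction"],
            "p_rxh": rxh["p_value"],
            "dir_rxh": rxh["direction"],
        },
        index=rx_results.index,
    )


def reference_set_overlap(calls: pd.DataFrame, refs: GeneSetCollection, *,
                          n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Membership fraction of each cis/trans category in each reference
    set, with preranked-GSEA significance on the contrast's logFC.

    ``calls`` is a classified DE table (columns ``category``, ``logFC``).
    """
    rows = []
    ranked = calls["logFC"]
    gsea = preranked_gsea(ranked, refs, n_perm=n_perm, seed=seed) if len(refs) else None
    for ref_name, genes in refs.items():
        if len(genes) == 0:
            raise ValueError(f"empty reference set {ref_name!r}")
        members = set(genes)
        for cat, sub in calls.groupby("category", observed=True):
            frac = float(np.mean([g in members for g in sub.index])) if len(sub) else np.nan
            rows.append((ref_name, str(cat), len(sub), frac))
    out = pd.DataFrame(rows, columns=["reference_set", "category", "n_genes", "fraction"])
    if gsea is not None and len(gsea):
        out = out.merge(
            gsea[["p_value", "p_adj"]], left_on="reference_set", right_index=True, how="left"
        )
    return out
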