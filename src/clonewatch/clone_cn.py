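"""Clone-level copy-number summaries and gene-to-bin mapping.

Per-cell integer copy-number calls on fixed genomic bins (DLP+-style,
500-kb non-overlapping windows) are summarized into per-clone median
profiles.  Those profiles are the genomic side of every in-cis decision
downstream: a gene sits "in cis" of a clone contrast when the clone
medians differ at the bin its coordinates overlap the most.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CNMatrix",
    "CloneProfileSet",
    "GeneBinMap",
    "clone_median_profiles",
    "manhattan_distance",
    "map_genes_to_bins",
]


@dataclass
class CNMatrix:
    """Per-cell integer copy states over fixed genomic bins.

    Parameters
    ----------
    bins : DataFrame with columns ``chrom``, ``start``, ``end`` —
        non-overlapping, sorted within chromosome, 0-based half-open.
    copy : DataFrame, cells x bins, integer copy states (columns align
        with ``bins`` rows by position).
    clone : Series mapping cell id -> clone label.
    """

    bins: pd.DataFrame
    copy: pd.DataFrame
    clone: pd.Series

    def __post_init__(self) -> None:
        if self.copy.shape[1] != len(self.bins):
            raise ValueError(
                f"copy matrix has {self.copy.shape[1]} columns but "
                f"{len(self.bins)} bins were supplied"
            )
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"malformed bin interval on {chrom}")
            order = np.argsort(starts)
            if np.any(ends[order][:-1] > starts[order][1:]):
                raise ValueError(f"overlapping bins on {chrom}")

    @property
    def cells(self) -> pd.Index:
        return self.copy.index

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class CloneProfileSet:
    """Per-clone median copy number per bin (median of an even number of
    integers is kept as an exact half-integer, never rounded)."""

    bins: pd.DataFrame
    median_cn: pd.DataFrame  # clones x bins
    n_cells: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def clones(self) -> list:
        return list(self.median_cn.index)


@dataclass
class GeneBinMap:
    """Gene -> most-overlapping bin.

    ``table`` columns: gene (index), chrom, start, end, bin (int index into
    the bin list, -1 when unmapped), overlap_bp, spans_boundary.
    """

    table: pd.DataFrame

    def bin_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "bin"])

    @property
    def mapped(self) -> pd.DataFrame:
        return self.table[self.table["bin"] >= 0]


def clone_median_profiles(cn: CNMatrix) -> CloneProfileSet:
    """Summarize per-cell copy states into per-clone per-bin medians.

    Raises if any clone label has zero member cells (a label present in
    the clone vector's categories but never used).
    """
    clone = cn.clone.reindex(cn.cells)
    if clone.isna().any():
        missing = list(cn.cells[clone.isna()][:5])
        raise ValueError(f"cells without clone label: {missing}")
    counts = clone.value_counts()
    empty = [c for c in counts.index if counts[c] == 0]
    if empty:
        raise ValueError(f"clones with 0 cells: {empty}")
    med = cn.copy.groupby(clone, observed=True).median()
    med = med.sort_index()
    return CloneProfileSet(bins=cn.bins, median_cn=med, n_cells=counts.sort_index())


def manhattan_distance(a, b, *, per_bin: bool = True) -> float:
    """Manhattan distance between two clone median profiles.

    By default the sum of absolute per-bin differences is divided by the
    number of bins ("average CNA distance"); ``per_bin=False`` returns
    the raw sum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"bin mismatch: {a.shape} vs {b.shape}")
    d = float(np.abs(a - b).sum())
    return d / a.size if per_bin else d


def map_genes_to_bins(genes: pd.DataFrame, bins: pd.DataFrame) -> GeneBinMap:
    """Assign every gene to the bin its coordinates overlap the most.

    Parameters
    ----------
    genes : DataFrame indexed by gene id with columns chrom, start, end
        (0-based half-open).
    bins : DataFrame with columns chrom, start, end; non-overlapping and
        sorted after canonical per-chromosome sorting (applied here, so
        input bin order does not matter; the returned ``bin`` column
        refers to positions in the *input* bin frame).

    A gene overlapping >= 2 bins gets ``spans_boundary=True``; equal
    overlap ties break toward the lower-coordinate bin.  Genes with no
    overlapping bin get bin = -1.
    """
    if (genes["end"] <= genes["start"]).any():
        bad = genes.index[genes["end"] <= genes["start"]][:5]
        raise ValueError(f"malformed gene intervals (end <= start): {list(bad)}")
    if (bins["end"] <= bins["start"]).any():
        raise ValueError("malformed bin interval (end <= start)")

    out = {}
    bins_idx = bins.reset_index(drop=True)
    for chrom, bgrp in bins_idx.groupby("chrom", sort=False):
        order = np.argsort(bgrp["start"].to_numpy(), kind="stable")
        starts = bgrp["start"].to_numpy()[order]
        ends = bgrp["end"].to_numpy()[order]
        orig = bgrp.index.to_numpy()[order]
        ggrp = genes[genes["chrom"] == chrom]
        for gene, row in ggrp.iterrows():
            gs, ge = int(row["start"]), int(row["end"])
            # candidate bins: those with start < ge and end > gs
            lo = int(np.searchsorted(ends, gs, side="right"))
            hi = int(np.searchsorted(starts, ge, side="left"))
            best_bin, best_ov, n_hit = -1, 0, 0
            for j in range(lo, hi):
                ov = min(ge, ends[j]) - max(gs, starts[j])
                if ov > 0:
                    n_hit += 1
                    if ov > best_ov:  # ties keep the earlier (lower-coord) bin
                        best_ov, best_bin = ov, int(orig[j])
            out[gene] = (row["chrom"], gs, ge, best_bin, best_ov, n_hit >= 2)
    tbl = pd.DataFrame.from_dict(
        out,
        orient="index",
        columns=["chrom", "start", "end", "bin", "overlap_bp", "spans_boundary"],
    )
    # genes on chromosomes with no bins at all
    missing = genes.index.difference(tbl.index)
    if len(missing):
        extra = genes.loc[missing, ["chrom", "start", "end"]].copy()
        extra["bin"] = -1
        extra["overlap_bp"] = 0
        extra["spans_boundary"] = False
        tbl = pd.concat([tbl, extra])
    tbl = tbl.reindex(genes.index)
    tbl["bin"] = tbl["bin"].astype(int)
    tbl["overlap_bp"] = tbl["overlap_bp"].astype(int)
    tbl["spans_boundary"] = tbl["spans_boundary"].astype(bool)
    return GeneBinMap(table=tbl)
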