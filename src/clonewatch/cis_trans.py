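"""Six-trend classification of differentially expressed genes.

A DE gene between two clones is *in-cis* when the clone median copy
numbers differ at the bin the gene overlaps the most, *in-trans*
otherwise.  In-cis genes split by the sign agreement between the copy
change (delta CN = median A - median B) and the expression change:

======== ========= ===============================
delta CN logFC     category
======== ========= ===============================
> 0      > 0       GainUp        (CN correlated)
< 0      < 0       LossDown      (CN correlated)
> 0      < 0       GainDown      (CN anti-correlated)
< 0      > 0       LossUp        (CN anti-correlated)
= 0      > 0       InTransUp
= 0      < 0       InTransDown
======== ========= ===============================

Medians are compared exactly (half-integers included); a configurable
``min_delta`` relaxes this to |delta CN| > min_delta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .clone_cn import CloneProfileSet, GeneBinMap

__all__ = [
    "CIS_CATEGORIES",
    "classify_cis_trans",
    "summarize_proportions",
    "boundary_overlap_fraction",
]

CIS_CATEGORIES = ("GainUp", "LossDown", "GainDown", "LossUp", "InTransUp", "InTransDown")


def classify_cis_trans(de: pd.DataFrame, gene_map: GeneBinMap,
                       profiles: CloneProfileSet, clone_a, clone_b,
                       *, min_delta: float = 0.0,
                       on_unmapped: str = "report") -> pd.DataFrame:
    """Classify significance-filtered DE genes into the six trends.

    ``de`` must already be filtered to the contrast's significance
    thresholds and indexed by gene.  Unmapped genes (no overlapping bin)
    are excluded; with ``on_unmapped="error"`` they raise instead.
    """
    if clone_a not in profiles.median_cn.index or clone_b not in profiles.median_cn.index:
        raise ValueError(f"clones {clone_a!r}/{clone_b!r} absent from profiles")
    med_a = profiles.median_cn.loc[clone_a].to_numpy()
    med_b = profiles.median_cn.loc[clone_b].to_numpy()

    missing = de.index.difference(gene_map.table.index)
    if len(missing):
        if on_unmapped == "error":
            raise KeyError(f"genes absent from the gene-bin map: {list(missing[:5])}")
        warnings.warn(f"{len(missing)} DE genes absent from the gene-bin map; excluded")
        de = de.drop(index=missing)

    sub = gene_map.table.loc[de.index]
    unmapped = sub["bin"] < 0
    if unmapped.any():
        if on_unmapped == "error":
            raise KeyError(f"unmapped genes: {list(sub.index[unmapped][:5])}")
        warnings.warn(f"{int(unmapped.sum())} DE genes map to no bin; excluded")
        de = de.loc[~unmapped.to_numpy()]
        sub = sub.loc[~unmapped.to_numpy()]

    zero_lfc = de["logFC"] == 0
    if zero_lfc.any():
        warnings.warn(f"{int(zero_lfc.sum())} genes with logFC exactly 0 excluded")
        de = de.loc[~zero_lfc]
        sub = sub.loc[~zero_lfc.to_numpy()]

    bins = sub["bin"].to_numpy()
    delta = med_a[bins] - med_b[bins]
    lfc = de["logFC"].to_numpy()
    is_cis = np.abs(delta) > min_delta

    category = np.where(
        is_cis,
        np.where(
            delta > 0,
            np.where(lfc > 0, "GainUp", "GainDown"),
            np.where(lfc < 0, "LossDown", "LossUp"),
        ),
        np.where(lfc > 0, "InTransUp", "InTransDown"),
    )
    correlated = pd.array(
        np.where(is_cis, np.isin(category, ["GainUp", "LossDown"]), None), dtype="boolean"
    )
    return pd.DataFrame(
        {
            "category": pd.Categorical(category, categories=list(CIS_CATEGORIES)),
            "is_cis": is_cis,
            "cn_correlated": correlated,
            "delta_cn": delta,
            "logFC": lfc,
            "chrom": sub["chrom"].to_numpy(),
            "spans_boundary": sub["spans_boundary"].to_numpy(),
        },
        index=de.index,
    )


def summarize_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Global and per-chromosome category fractions (sum to 1 per stratum)."""
    if calls.empty:
        raise ValueError("no classified genes to summarize")

    def frac(sub: pd.DataFrame, stratum: str) -> dict:
        counts = sub["category"].value_counts()
        total = counts.sum()
        row = {"stratum": stratum, "n_genes": int(total)}
        for cat in CIS_CATEGORIES:
            row[cat] = counts.get(cat, 0) / total
        row["in_cis"] = sub["is_cis"].mean()
        row["anti_correlated"] = float((sub["cn_correlated"] == False).sum()) / total  # noqa: E712
        return row

    rows = [frac(calls, "all")]
    for chrom, sub in calls.groupby("chrom", sort=False, observed=True):
        rows.append(frac(sub, str(chrom)))
    return pd.DataFrame(rows).set_index("stratum")


def boundary_overlap_fraction(calls: pd.DataFrame,
                              gene_map: GeneBinMap | None = None) -> float:
    """Fraction of CN anti-correlated genes whose body straddles a bin
    boundary — the diagnostic for boundary mis-calls masquerading as
    counter-regulation.  Returns NaN (with a warning) when there are no
    anti-correlated genes.
    """
    anti = calls[calls["cn_correlated"] == False]  # noqa: E712
    if len(anti) == 0:
        warnings.warn("no anti-correlated genes; boundary fraction undefined")
        return float("nan")
    if "spans_boundary" in anti.columns:
        spans = anti["spans_boundary"]
    else:
        if gene_map is None:
            raise ValueError("gene_map required when calls lack spans_boundary")
        spans = gene_map.table.loc[anti.index, "spans_boundary"]
    return float(np.mean(spans.to_numpy(dtype=bool)))
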