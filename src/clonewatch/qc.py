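"""Cell-level quality control for xenograft scRNA-seq.

Xenograft dissociates carry mouse stromal cells and damaged cells; the
filters here reproduce the standard four-rule retention criterion used
for such data:

1. at least ``min_genes`` detected (nonzero) human genes,
2. mitochondrial UMI fraction below ``max_mito_frac``,
3. ribosomal UMI fraction below ``max_ribo_frac``,
4. total UMI count no more than ``mad_k`` median absolute deviations
   below the overall median total.

Mouse cells are removed first by a strict majority-of-counts rule
against the mouse feature namespace.  Doublet flags, when present in
``obs``, are consumed as metadata (no detection is performed here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = ["QCThresholds", "QCReport", "flag_mouse_cells", "qc_filter"]

MAD_CONSISTENCY = 1.4826  # Gaussian consistency constant (scater isOutlier default)


@dataclass
class QCThresholds:
    min_genes: int = 1000
    max_mito_frac: float = 0.20
    max_ribo_frac: float = 0.60
    mad_k: float = 3.0
    drop_doublets: bool = True
    scale_mad: bool = True  # disable to use the raw (unscaled) MAD
    mito_pattern: str = r"^MT-"
    ribo_pattern: str = r"^(?:RPL|RPS)"
    mouse_pattern: str = r"^mm_"

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_frac <= 1 or not 0 <= self.max_ribo_frac <= 1:
            raise ValueError("mito/ribo fractions must lie in [0, 1]")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be > 0")


@dataclass
class QCReport:
    """Removal counts per criterion (a cell may fail several) plus net."""

    n_input: int = 0
    n_mouse: int = 0
    n_doublet: int = 0
    failed_min_genes: int = 0
    failed_mito: int = 0
    failed_ribo: int = 0
    failed_low_count: int = 0
    n_removed: int = 0
    n_retained: int = 0
    thresholds: QCThresholds | None = None
    count_median: float = float("nan")
    count_mad: float = float("nan")
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {
            k: getattr(self, k)
            for k in (
                "n_input", "n_mouse", "n_doublet", "failed_min_genes",
                "failed_mito", "failed_ribo", "failed_low_count",
                "n_removed", "n_retained",
            )
        }
        return pd.DataFrame({"criterion": list(d), "count": list(d.values())})


def flag_mouse_cells(human_counts, mouse_counts) -> np.ndarray:
    """True iff the mouse-aligned total strictly exceeds the human total.

    Ties count as human: a cell is only discarded as mouse when the
    evidence is strictly in the mouse reference's favor.
    """
    h = np.asarray(human_counts, dtype=float)
    m = np.asarray(mouse_counts, dtype=float)
    if h.shape != m.shape:
        raise ValueError(f"length mismatch: {h.shape} vs {m.shape}")
    if np.any(h < 0) or np.any(m < 0):
        raise ValueError("counts must be nonnegative")
    return m > h


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def qc_filter(adata: AnnData, th: QCThresholds | None = None,
              *, frozen_median: bool = True) -> tuple[AnnData, QCReport]:
    """Apply the mouse rule then the four retention criteria.

    Detected genes and count totals are evaluated on human (non-mouse)
    features only, after mouse-cell removal.  With ``frozen_median``
    (the default) the low-count rule's median/MAD are those of the
    first evaluation over the post-mouse cells, which makes the filter
    idempotent; re-evaluated mode recomputes them on whatever cells are
    passed in.

    Returns the filtered AnnData (a copy; retained cells' counts are
    untouched) and a :class:`QCReport`.
    """
    th = th or QCThresholds()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty expression matrix")
    names = adata.var_names.astype(str)
    is_mouse_gene = names.str.contains(th.mouse_pattern, regex=True)
    is_mito = names.str.contains(th.mito_pattern, regex=True) & ~is_mouse_gene
    is_ribo = names.str.contains(th.ribo_pattern, regex=True) & ~is_mouse_gene
    if not is_mito.any():
        raise ValueError(
            f"no mitochondrial genes match pattern {th.mito_pattern!r}; "
            "mito annotation is required for QC"
        )

    X = _dense(adata.X)
    report = QCReport(n_input=adata.n_obs, thresholds=th)

    human_total = X[:, ~is_mouse_gene].sum(1)
    mouse_total = X[:, is_mouse_gene].sum(1)
    mouse_cell = flag_mouse_cells(human_total, mouse_total)
    report.n_mouse = int(mouse_cell.sum())

    keep = ~mouse_cell
    if th.drop_doublets and "is_doublet" in adata.obs:
        doublet = adata.obs["is_doublet"].to_numpy(dtype=bool)
        report.n_doublet = int((doublet & keep).sum())
        keep &= ~doublet

    Xh = X[:, ~is_mouse_gene]
    total = Xh.sum(1)
    detected = (Xh > 0).sum(1)
    mito_frac = np.divide(X[:, is_mito].sum(1), total, out=np.ones_like(total, dtype=float),
                          where=total > 0)
    ribo_frac = np.divide(X[:, is_ribo].sum(1), total, out=np.zeros_like(total, dtype=float),
                          where=total > 0)

    if frozen_median and "qc_count_median" in adata.uns:
        med, mad = adata.uns["qc_count_median"], adata.uns["qc_count_mad"]
    else:
        med = float(np.median(total[keep]))
        mad = float(np.median(np.abs(total[keep] - med)))
        if th.scale_mad:
            mad *= MAD_CONSISTENCY
    report.count_median, report.count_mad = med, mad
    low_cut = med - th.mad_k * mad

    f_genes = detected < th.min_genes
    f_mito = mito_frac >= th.max_mito_frac
    f_ribo = ribo_frac >= th.max_ribo_frac
    f_low = total < low_cut
    report.failed_min_genes = int((f_genes & keep).sum())
    report.failed_mito = int((f_mito & keep).sum())
    report.failed_ribo = int((f_ribo & keep).sum())
    report.failed_low_count = int((f_low & keep).sum())

    keep &= ~(f_genes | f_mito | f_ribo | f_low)
    report.n_retained = int(keep.sum())
    report.n_removed = report.n_input - report.n_retained

    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    out.obs["total_counts"] = total[keep]
    out.obs["mito_frac"] = mito_frac[keep]
    out.obs["ribo_frac"] = ribo_frac[keep]
    if frozen_median:
        out.uns["qc_count_median"] = med
        out.uns["qc_count_mad"] = mad
    return out, report
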