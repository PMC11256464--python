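"""Treatment-response gene dynamics across drug exposure and withdrawal.

Two selections over a pair of contrasts on the same gene universe:

* **Stable response genes** — differentially expressed on drug versus
  untreated (FDR < ``de_fdr`` and |logFC| > ``de_lfc``) yet *not*
  differentially expressed on drug versus holiday (FDR > ``stable_fdr``):
  expression shifted by treatment and held there through withdrawal.
  The shift direction labels them induced (logFC > de_lfc) or repressed
  (logFC < -de_lfc).

* **Holiday-diverged genes** — differentially expressed on drug versus
  holiday; their direction of travel is read off the sign agreement with
  the drug-versus-untreated contrast: same sign means the withdrawal
  moved expression back *toward* the untreated state, opposite sign (or
  an exactly-zero reference logFC) means it moved *away* into a new
  state.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["stable_response_genes", "holiday_divergence"]

log = logging.getLogger(__name__)

DE_FDR = 0.01
DE_LFC = 0.5
STABLE_FDR = 0.1


def _intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.Index:
    shared = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(shared)
    if dropped:
        log.info("%d genes present in only one contrast excluded", dropped)
    return shared


def stable_response_genes(de_rx_unrx: pd.DataFrame, de_rx_rxh: pd.DataFrame,
                          *, de_fdr: float = DE_FDR, de_lfc: float = DE_LFC,
                          stable_fdr: float = STABLE_FDR) -> pd.DataFrame:
    """Genes induced or repressed by treatment and stable on holiday.

    Both inputs are full DE tables (gene-indexed, columns ``logFC`` and
    ``fdr``); only their shared gene universe is considered.
    """
    if stable_fdr <= de_fdr:
        raise ValueError(
            f"stable_fdr ({stable_fdr}) must exceed de_fdr ({de_fdr}): the "
            "stability rule is a *non*-significance requirement"
        )
    shared = _intersect(de_rx_unrx, de_rx_rxh)
    a = de_rx_unrx.loc[shared]
    b = de_rx_rxh.loc[shared]
    sig = (a["fdr"] < de_fdr) & (a["logFC"].abs() > de_lfc)
    stable = b["fdr"] > stable_fdr
    keep = sig & stable
    out = pd.DataFrame(
        {
            "class": np.where(a.loc[keep, "logFC"] > de_lfc, "induced", "repressed"),
            "logFC_rx_unrx": a.loc[keep, "logFC"],
            "fdr_rx_unrx": a.loc[keep, "fdr"],
            "logFC_rx_rxh": b.loc[keep, "logFC"],
            "fdr_rx_rxh": b.loc[keep, "fdr"],
        }
    )
    return out


def holiday_divergence(de_rx_rxh: pd.DataFrame, de_rx_unrx: pd.DataFrame,
                       *, de_fdr: float = DE_FDR, de_lfc: float = DE_LFC
                       ) -> pd.DataFrame:
    """Genes that moved on withdrawal, labeled toward/away from untreated.

    ``de_rx_rxh`` is filtered here at (de_fdr, de_lfc); the significant
    set is intersected with the full ``de_rx_unrx`` gene universe to
    read the reference direction.  A reference logFC of exactly zero has
    no shared sign and is classified ``diverged_away`` (logged).
    """
    sig = de_rx_rxh[(de_rx_rxh["fdr"] < de_fdr) & (de_rx_rxh["logFC"].abs() > de_lfc)]
    shared = sig.index.intersection(de_rx_unrx.index)
    if len(shared) == 0:
        warnings.warn("no overlap between the holiday-diverged set and the "
                      "untreated contrast's gene universe")
        return pd.DataFrame(
            columns=["class", "logFC_rx_rxh", "fdr_rx_rxh", "logFC_rx_unrx", "fdr_rx_unrx"]
        )
    a = sig.loc[shared]
    ref = de_rx_unrx.loc[shared]
    zero_ref = ref["logFC"] == 0
    if zero_ref.any():
        log.info("%d genes with reference logFC exactly 0 classified away", int(zero_ref.sum()))
    toward = np.sign(a["logFC"]) == np.sign(ref["logFC"])
    toward &= ~zero_ref
    return pd.DataFrame(
        {
            "class": np.where(toward, "diverged_toward", "diverged_away"),
            "logFC_rx_rxh": a["logFC"],
            "fdr_rx_rxh": a["fdr"],
            "logFC_rx_unrx": ref["logFC"],
            "fdr_rx_unrx": ref["fdr"],
        }
    )
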