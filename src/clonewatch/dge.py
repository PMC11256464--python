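"""Negative-binomial differential expression between two cell groups.

Self-contained two-group NB Wald test with empirical-Bayes dispersion
shrinkage, used for all pairwise clone/condition contrasts:

* library-size effects removed through median-scaled size factors used
  as offsets;
* per-gene NB dispersion (Var = mu + alpha * mu^2) estimated by moments
  on size-factor-adjusted counts, then shrunk toward a mean-dispersion
  trend with a prior weight of 20 pseudo-observations;
* Wald test on the difference of log group means, two-sided normal p,
  Benjamini-Hochberg FDR over the tested genes.

Positive log2 fold change means higher expression in group A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "de_test", "benjamini_hochberg"]

PRIOR_WEIGHT = 20.0  # pseudo-observations pulling dispersion toward the trend
LOGFC_PSEUDO = 0.5  # added to a zero group mean before the log2 ratio
EXPRESSION_FLOOR = 0.01  # test genes nonzero in >=1 % of either group's cells


def _counts(x) -> np.ndarray:
    if isinstance(x, AnnData):
        x = x.X
    return (x.toarray() if hasattr(x, "toarray") else np.asarray(x)).astype(float)


def size_factors(expr) -> np.ndarray:
    """Per-cell scaling factor: total counts over the median total."""
    X = _counts(expr)
    total = X.sum(1)
    if np.all(total == 0):
        raise ValueError("all cells have zero counts")
    if np.any(total == 0):
        bad = np.where(total == 0)[0][:5]
        raise ValueError(f"all-zero cells at positions {list(bad)}")
    return total / np.median(total)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _moment_dispersion(Y: np.ndarray, mu: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Method-of-moments alpha per gene from one group's adjusted counts.

    Y are raw counts (cells x genes), mu the group mean on the common
    scale, sf the cells' size factors.  Var(y_cg) = sf_c mu + alpha sf_c^2 mu^2.
    """
    n = Y.shape[0]
    resid2 = (Y - sf[:, None] * mu[None, :]) ** 2
    num = resid2.sum(0) - (sf.sum() * mu)
    den = (sf**2).sum() * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 0.0, 100.0) * n / max(n - 1, 1)


def _trend(alpha: np.ndarray, log_mean: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean dispersion per log-mean bin, evaluated back at each gene."""
    edges = np.quantile(log_mean, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, log_mean, side="right") - 1, 0, len(edges) - 2)
    out = np.empty_like(alpha)
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.any():
            out[mask] = alpha[mask].mean()
    return out


def de_test(expr, group_a, group_b, *, min_cells: int = 2,
            size_factor_values: np.ndarray | None = None) -> pd.DataFrame:
    """Two-group NB Wald differential expression.

    Parameters
    ----------
    expr : AnnData or array-like counts, cells x genes.
    group_a, group_b : disjoint boolean masks, integer positions, or
        (for AnnData) obs-name lists selecting the two cell groups.
    min_cells : minimum cells per group.

    Returns a DataFrame indexed by gene with columns ``logFC`` (log2,
    A over B), ``p_value``, ``fdr``, ``mean_a``, ``mean_b`` for the
    genes passing the expression floor.
    """
    if isinstance(expr, AnnData):
        genes = expr.var_names
        X = _counts(expr)
        def resolve(g):
            g = np.asarray(g)
            if g.dtype == bool:
                return g
            if g.dtype.kind in "iu":
                m = np.zeros(X.shape[0], dtype=bool)
                m[g] = True
                return m
            return expr.obs_names.isin(g)
    else:
        X = _counts(expr)
        genes = pd.Index([f"g{i}" for i in range(X.shape[1])])
        def resolve(g):
            g = np.asarray(g)
            if g.dtype == bool:
                return g
            m = np.zeros(X.shape[0], dtype=bool)
            m[g] = True
            return m

    ma, mb = resolve(group_a), resolve(group_b)
    if np.any(ma & mb):
        raise ValueError("groups overlap")
    na, nb = int(ma.sum()), int(mb.sum())
    if na < min_cells or nb < min_cells:
        raise ValueError(f"groups too small: {na}, {nb} (min_cells={min_cells})")

    both = ma | mb
    sf = size_factors(X[both]) if size_factor_values is None else np.asarray(size_factor_values)[both]
    sub = X[both]
    ma_s, mb_s = ma[both], mb[both]

    floor = np.maximum(
        (sub[ma_s] > 0).mean(0), (sub[mb_s] > 0).mean(0)
    ) >= EXPRESSION_FLOOR
    if not floor.any():
        raise ValueError("gene universe empty after expression floor")
    sub = sub[:, floor]
    genes = genes[floor]

    Ya, Yb = sub[ma_s], sub[mb_s]
    sfa, sfb = sf[ma_s], sf[mb_s]
    mu_a = Ya.sum(0) / sfa.sum()
    mu_b = Yb.sum(0) / sfb.sum()

    # dispersion: pooled moment estimates, shrunk toward the mean trend
    alpha_a = _moment_dispersion(Ya, mu_a, sfa)
    alpha_b = _moment_dispersion(Yb, mu_b, sfb)
    alpha_raw = (na * alpha_a + nb * alpha_b) / (na + nb)
    mu_pool = (Ya.sum(0) + Yb.sum(0)) / (sfa.sum() + sfb.sum())
    log_mean = np.log(mu_pool + 1e-8)
    alpha_trend = _trend(alpha_raw, log_mean)
    df = na + nb - 2
    alpha = (df * alpha_raw + PRIOR_WEIGHT * alpha_trend) / (df + PRIOR_WEIGHT)

    # Wald on log-mean difference; delta-method variance of log(mu_hat)
    def log_mean_var(Y, sfg, mu):
        mu_safe = np.maximum(mu, 1e-8)
        var_hat = (sfg.sum() * mu_safe + alpha * (sfg**2).sum() * mu_safe**2) / sfg.sum() ** 2
        return var_hat / mu_safe**2

    va = log_mean_var(Ya, sfa, mu_a)
    vb = log_mean_var(Yb, sfb, mu_b)
    la = np.log(np.where(mu_a > 0, mu_a, LOGFC_PSEUDO / sfa.sum()))
    lb = np.log(np.where(mu_b > 0, mu_b, LOGFC_PSEUDO / sfb.sum()))
    z = (la - lb) / np.sqrt(va + vb)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = benjamini_hochberg(p)
    # pseudo-counted log2 ratio when a group mean is exactly zero
    logfc = np.log2((mu_a + (mu_a == 0) * LOGFC_PSEUDO) / (mu_b + (mu_b == 0) * LOGFC_PSEUDO))

    return pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": p,
            "fdr": fdr,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "dispersion": alpha,
        },
        index=pd.Index(genes, name="gene"),
    )
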