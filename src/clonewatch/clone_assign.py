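"""Dosage-based assignment of scRNA-seq cells to copy-number clones.

A cell's transcriptome carries a genomic fingerprint: for most genes,
more genomic copies mean proportionally more transcripts.  Given clone
median copy-number profiles from single-cell WGS, each scRNA-seq cell is
assigned to the clone whose dosage profile best explains its counts.

The model here is a finite mixture of multinomials: cell ``c`` of clone
``k`` draws its counts over the selected informative genes as
``Multinomial(N_c, pi_k)`` with ``pi_kg ∝ mu_g * d_gk`` where ``mu_g``
is a shared per-gene expression level and ``d_gk`` the clone's copy
number at the gene's bin (clipped at a saturation threshold; copy 0 is
mapped to a small pseudo-dosage for numerical robustness).  Fitting is
EM with a closed-form minorization step for ``mu`` — the observed
log-likelihood is non-decreasing every iteration — restarted
``n_restarts`` times from jittered initializations.

Only high-confidence genes enter the model: a gene is used when, in
every clone, at least ``cn_purity`` of the clone's cells carry the modal
copy number at the gene's bin, and the clone modal copy numbers are not
all equal (otherwise the gene carries no dosage signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.special import logsumexp
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .clone_cn import CNMatrix, CloneProfileSet, GeneBinMap

__all__ = [
    "AssignmentParams",
    "CloneAssignment",
    "CloneAssignEM",
    "select_assignment_genes",
    "assign_clones",
    "proportion_concordance",
]

PSEUDO_DOSAGE = 0.1  # stands in for copy 0 (a multinomial cannot hold exact zeros)


@dataclass
class AssignmentParams:
    cn_purity: float = 0.6
    min_counts_per_cell: int = 25
    max_cn: int = 6
    n_restarts: int = 3
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    min_posterior: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.cn_purity <= 1:
            raise ValueError("cn_purity must lie in (0, 1]")
        if self.max_cn < 2:
            raise ValueError("max_cn must be >= 2")


@dataclass
class CloneAssignment:
    """Per-cell clone call with full posterior."""

    assignments: pd.Series  # cell -> clone label ("unassigned" below min_posterior)
    posterior: pd.DataFrame  # cells x clones, rows sum to 1
    genes_used: list
    log_likelihood_trace: np.ndarray
    dropped_cells: pd.Index = field(default_factory=lambda: pd.Index([]))


def select_assignment_genes(cn: CNMatrix, profiles: CloneProfileSet,
                            gene_map: GeneBinMap, params: AssignmentParams | None = None
                            ) -> list[str]:
    """Keep genes whose bin shows a pure, informative dosage contrast.

    For every clone the fraction of its cells carrying the modal copy
    number at the gene's bin must reach ``cn_purity``; clone modal
    copy numbers (clipped at ``max_cn``) must not all be equal.
    """
    params = params or AssignmentParams()
    clone = cn.clone.reindex(cn.cells)
    copy = cn.copy.to_numpy()
    clones = profiles.clones

    # per clone x bin: modal CN and the fraction of cells at the mode
    modal = np.zeros((len(clones), cn.n_bins))
    purity = np.zeros((len(clones), cn.n_bins))
    for i, k in enumerate(clones):
        sub = copy[(clone == k).to_numpy()]
        for b in range(cn.n_bins):
            vals, counts = np.unique(sub[:, b], return_counts=True)
            j = int(np.argmax(counts))
            modal[i, b] = vals[j]
            purity[i, b] = counts[j] / sub.shape[0]

    kept = []
    mapped = gene_map.mapped
    for gene, row in mapped.iterrows():
        b = int(row["bin"])
        if np.any(purity[:, b] < params.cn_purity):
            continue
        clipped = np.minimum(modal[:, b], params.max_cn)
        if np.all(clipped == clipped[0]):
            continue  # uninformative: no dosage signal
        kept.append(gene)
    if not kept:
        raise ValueError(
            "no genes pass the purity/informativeness filters; "
            "consider lowering cn_purity"
        )
    return kept


class CloneAssignEM(BaseEstimator, ClassifierMixin):
    """EM mixture-of-multinomials clone classifier.

    Parameters mirror :class:`AssignmentParams`.  ``fit`` takes the
    count matrix over the selected genes (cells x genes) plus the clone
    dosage matrix; ``predict`` returns clone labels, ``predict_proba``
    the posterior responsibilities.

    Attributes (after fit)
    ----------------------
    mu_ : ndarray, shared per-gene expression levels (sum 1).
    priors_ : ndarray, mixture weights.
    responsibilities_ : ndarray, cells x clones posterior.
    labels_ : ndarray of clone labels per cell.
    log_likelihood_trace_ : ndarray, best restart's trace (non-decreasing).
    """

    def __init__(self, cn_purity: float = 0.6, min_counts_per_cell: int = 25,
                 max_cn: int = 6, n_restarts: int = 3, max_iter: int = 500,
                 tol: float = 1e-6, random_state: int = 0, min_posterior: float = 0.0):
        self.cn_purity = cn_purity
        self.min_counts_per_cell = min_counts_per_cell
        self.max_cn = max_cn
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.min_posterior = min_posterior

    # -- internals ---------------------------------------------------------

    def _dosage(self, clone_cn: np.ndarray) -> np.ndarray:
        d = np.minimum(np.asarray(clone_cn, dtype=float), self.max_cn)
        d[d == 0] = PSEUDO_DOSAGE
        return d

    def _log_lik(self, X, log_pi, log_prior):
        # cells x clones complete log-likelihood (multinomial coefficient dropped)
        return X @ log_pi.T + log_prior[None, :]

    def fit(self, X, clone_cn, clone_labels=None):
        """Fit the mixture.

        Parameters
        ----------
        X : (n_cells, n_genes) count matrix over the selected genes.
        clone_cn : (n_clones, n_genes) clone copy numbers at each gene's
            bin (may be half-integer medians).
        clone_labels : optional clone names (defaults to 0..K-1).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x genes)")
        if X.shape[1] == 0:
            raise ValueError("empty gene list")
        if X.shape[0] == 0:
            raise ValueError("no cells to assign (all below min_counts_per_cell?)")
        clone_cn = np.asarray(clone_cn, dtype=float)
        n_clones = clone_cn.shape[0]
        self.clone_labels_ = (
            np.asarray(clone_labels) if clone_labels is not None else np.arange(n_clones)
        )
        d = self._dosage(clone_cn)  # K x G
        N = X.sum(1)

        if n_clones == 1:
            self.responsibilities_ = np.ones((X.shape[0], 1))
            self.priors_ = np.array([1.0])
            self.mu_ = X.sum(0) / max(X.sum(), 1)
            self.labels_ = self.clone_labels_[np.zeros(X.shape[0], dtype=int)]
            self.log_likelihood_trace_ = np.array([0.0])
            return self

        rng = np.random.default_rng(self.random_state)
        pooled = X.sum(0) + 1e-9
        best = None
        for restart in range(self.n_restarts):
            mu = pooled / pooled.sum()
            if restart > 0:
                mu = mu * rng.lognormal(0.0, 0.1, mu.size)
                mu /= mu.sum()
            prior = np.full(n_clones, 1.0 / n_clones)
            trace = []
            prev_ll = -np.inf
            for _ in range(self.max_iter):
                pi = mu[None, :] * d  # K x G unnormalized
                Z = pi.sum(1, keepdims=True)
                log_pi = np.log(pi) - np.log(Z)
                ll_ck = self._log_lik(X, log_pi, np.log(prior))
                norm = logsumexp(ll_ck, axis=1)
                ll = float(norm.sum())
                trace.append(ll)
                r = np.exp(ll_ck - norm[:, None])  # responsibilities
                # M-step: priors closed form; mu by one MM (minorize) step,
                # which cannot decrease the observed log-likelihood
                prior = r.mean(0)
                prior = np.clip(prior, 1e-12, None)
                prior /= prior.sum()
                W = r.T @ N  # per-clone effective total counts
                denom = (W[:, None] / Z * d).sum(0)
                mu = pooled / np.clip(denom, 1e-300, None)
                mu /= mu.sum()
                if ll - prev_ll < self.tol * max(abs(ll), 1.0) and len(trace) > 2:
                    prev_ll = ll
                    break
                prev_ll = ll
            if best is None or prev_ll > best[0]:
                best = (prev_ll, mu, prior, np.array(trace))
        _, mu, prior, trace = best
        pi = mu[None, :] * d
        log_pi = np.log(pi) - np.log(pi.sum(1, keepdims=True))
        ll_ck = self._log_lik(X, log_pi, np.log(prior))
        norm = logsumexp(ll_ck, axis=1)
        self.responsibilities_ = np.exp(ll_ck - norm[:, None])
        self.mu_ = mu
        self.priors_ = prior
        self.log_likelihood_trace_ = trace
        idx = np.argmax(self.responsibilities_, axis=1)
        self.labels_ = self.clone_labels_[idx]
        return self

    def predict_proba(self, X=None):
        check_is_fitted(self, "responsibilities_")
        if X is None:
            return self.responsibilities_
        raise NotImplementedError("out-of-sample scoring is not supported; refit instead")

    def predict(self, X=None):
        check_is_fitted(self, "labels_")
        if X is not None:
            raise NotImplementedError("out-of-sample scoring is not supported; refit instead")
        post = self.responsibilities_.max(1)
        labels = self.labels_.astype(object).copy()
        labels[post < self.min_posterior] = "unassigned"
        return labels


def assign_clones(adata: AnnData, profiles: CloneProfileSet, genes: list[str],
                  params: AssignmentParams | None = None,
                  gene_map: GeneBinMap | None = None) -> CloneAssignment:
    """Run the EM classifier on an AnnData over the selected genes.

    Cells whose total count over the selected genes falls below
    ``min_counts_per_cell`` are dropped and reported, never assigned.
    """
    params = params or AssignmentParams()
    if gene_map is None:
        raise ValueError("gene_map is required to look up clone CN per gene")
    genes = [g for g in genes if g in adata.var_names]
    if not genes:
        raise ValueError("empty gene list")
    sub = adata[:, genes]
    X = sub.X.toarray() if hasattr(sub.X, "toarray") else np.asarray(sub.X)
    X = X.astype(float)
    totals = X.sum(1)
    ok = totals >= params.min_counts_per_cell
    dropped = adata.obs_names[~ok]
    X = X[ok]

    bins = gene_map.table.loc[genes, "bin"].to_numpy()
    clone_cn = profiles.median_cn.to_numpy()[:, bins]
    est = CloneAssignEM(
        cn_purity=params.cn_purity, min_counts_per_cell=params.min_counts_per_cell,
        max_cn=params.max_cn, n_restarts=params.n_restarts, max_iter=params.max_iter,
        tol=params.tol, random_state=params.seed, min_posterior=params.min_posterior,
    )
    est.fit(X, clone_cn, clone_labels=profiles.clones)
    cells = adata.obs_names[ok]
    posterior = pd.DataFrame(est.responsibilities_, index=cells, columns=profiles.clones)
    assignments = pd.Series(est.predict(), index=cells, name="clone")
    return CloneAssignment(
        assignments=assignments, posterior=posterior, genes_used=genes,
        log_likelihood_trace=est.log_likelihood_trace_, dropped_cells=dropped,
    )


def proportion_concordance(assign: CloneAssignment, cn: CNMatrix,
                           sample_of_cell: pd.Series) -> tuple[pd.DataFrame, float]:
    """Compare inferred clonal proportions (expression side) with the
    clone-label proportions of the CN modality, per sample.

    Returns the long table of (sample, clone, proportion_rna,
    proportion_cn) points and the overall Pearson r across them.
    """
    clones = sorted(set(assign.posterior.columns) & set(cn.clone.unique()))
    if not clones:
        raise ValueError("no shared clone labels between the two modalities")

    rows = []
    rna = pd.DataFrame({"clone": assign.assignments, "sample": sample_of_cell.reindex(assign.assignments.index)})
    rna = rna[rna["clone"] != "unassigned"]
    dna = pd.DataFrame({"clone": cn.clone, "sample": sample_of_cell.reindex(cn.cells)})
    for sample in sorted(set(rna["sample"].dropna()) & set(dna["sample"].dropna())):
        r_sub = rna[rna["sample"] == sample]["clone"].value_counts(normalize=True)
        d_sub = dna[dna["sample"] == sample]["clone"].value_counts(normalize=True)
        for k in clones:
            rows.append((sample, k, float(r_sub.get(k, 0.0)), float(d_sub.get(k, 0.0))))
    table = pd.DataFrame(rows, columns=["sample", "clone", "proportion_rna", "proportion_cn"])
    if len(table) == 0:
        raise ValueError("no shared samples between the two modalities")
    if len(table) < 2 or table["proportion_cn"].nunique() == 1:
        vals_close = np.allclose(
            table["proportion_rna"].to_numpy(dtype=float),
            table["proportion_cn"].to_numpy(dtype=float),
        )
        r = 1.0 if vals_close else float("nan")
    else:
        r = float(pearsonr(table["proportion_rna"], table["proportion_cn"])[0])
    return table, r
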