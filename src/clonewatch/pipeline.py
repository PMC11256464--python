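"""End-to-end orchestration: QC -> clone assignment -> per-contrast DE ->
cis/trans -> dynamics -> enrichment -> trajectory -> chromatin.

Every stage output is a provenance-stamped TSV under the run directory;
rerunning with the same configuration and seed is bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin as chrom_mod
from . import cis_trans, dge, dynamics, enrichment, qc, trajectory
from .clone_assign import (AssignmentParams, assign_clones, proportion_concordance,
                           select_assignment_genes)
from .clone_cn import clone_median_profiles, map_genes_to_bins
from .io import (PipelineConfig, config_hash, read_cn_long, read_counts_mtx,
                 read_gmt, read_metadata, read_promoter_counts, write_tsv)
from .simulate import SimulationParams, simulate_chip_counts, simulate_dataset

__all__ = ["load_inputs", "select_contrast_clones", "run_pipeline"]

log = logging.getLogger(__name__)


def load_inputs(cfg: PipelineConfig):
    """Load (or simulate) all pipeline inputs as validated objects.

    Cross-checks: cell-id overlap between the CN and expression
    modalities is reported; duplicate gene ids raise at read time.
    """
    cfg.validate()
    if cfg.simulate:
        params = SimulationParams(**cfg.simulation, seed=cfg.seed)
        truth, cn, adata = simulate_dataset(params)
        gene_sets = _planted_gene_sets(truth)
        promoters = simulate_chip_counts(truth, params)
        return adata, cn, truth.genes, gene_sets, promoters, truth
    adata = read_counts_mtx(cfg.counts_dir)
    meta = read_metadata(cfg.metadata_path)
    adata.obs = adata.obs.join(meta, how="left")
    cn = read_cn_long(cfg.cn_path)
    overlap = len(set(adata.obs_names) & set(cn.cells))
    log.info("cell-id overlap between CN and expression: %d", overlap)
    genes = None
    if cfg.genes_bed:
        from .io import read_bed
        genes = read_bed(cfg.genes_bed)
    gene_sets = read_gmt(cfg.gene_sets_gmt) if cfg.gene_sets_gmt else None
    promoters = read_promoter_counts(cfg.promoter_counts) if cfg.promoter_counts else None
    return adata, cn, genes, gene_sets, promoters, None


def _planted_gene_sets(truth) -> enrichment.GeneSetCollection:
    """Gene sets derived from the planted programs, GMT-shaped."""
    sets = {}
    for program in ("induced_fixed", "induced_reversible",
                    "repressed_fixed", "repressed_reversible"):
        genes = list(truth.genes.index[truth.genes["program"] == program])
        if genes:
            sets[f"PLANTED_{program.upper()}"] = genes
    induced = list(truth.genes.index[truth.genes["program"].str.startswith("induced")])
    if induced:
        sets["PLANTED_RESISTANCE"] = induced
    return enrichment.GeneSetCollection(sets=sets)


def select_contrast_clones(assignments: pd.Series, metadata: pd.DataFrame,
                           *, min_cells: int = 100,
                           fitness: dict | None = None) -> list[dict]:
    """Pick the clone to carry each (passage, condition-pair) contrast.

    Per passage and condition, the fittest clone (when a fitness map is
    given) or the most abundant one is chosen, subject to carrying at
    least ``min_cells`` assigned cells; contrasts without a qualifying
    clone on both sides are skipped with a log message.
    """
    df = pd.DataFrame({"clone": assignments}).join(metadata[["condition", "passage"]])
    df = df[df["clone"] != "unassigned"]
    contrasts = []
    pairs = [("Rx", "UnRx"), ("RxH", "UnRx"), ("Rx", "RxH")]
    for passage in sorted(df["passage"].unique()):
        sub = df[df["passage"] == passage]
        picks = {}
        for cond, csub in sub.groupby("condition", observed=True):
            counts = csub["clone"].value_counts()
            eligible = counts[counts >= min_cells]
            if eligible.empty:
                continue
            if fitness:
                picks[cond] = max(eligible.index, key=lambda c: fitness.get(c, -np.inf))
            else:
                picks[cond] = eligible.index[0]  # most abundant
        for a, b in pairs:
            if a in picks and b in picks:
                contrasts.append(
                    {"passage": int(passage), "cond_a": a, "cond_b": b,
                     "clone_a": picks[a], "clone_b": picks[b]}
                )
            else:
                log.info("contrast %s vs %s at passage %s skipped "
                         "(no clone with >=%d cells)", a, b, passage, min_cells)
    return contrasts


def _contrast_de(adata, assignments, metadata, contrast, de_cfg):
    sel = pd.DataFrame({"clone": assignments}).join(metadata[["condition", "passage"]])
    def cells(cond, clone):
        m = ((sel["condition"] == cond) & (sel["passage"] == contrast["passage"])
             & (sel["clone"] == clone))
        return sel.index[m.fillna(False)]
    a = cells(contrast["cond_a"], contrast["clone_a"])
    b = cells(contrast["cond_b"], contrast["clone_b"])
    return dge.de_test(adata, list(a), list(b))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    stamp = dict(seed=cfg.seed, cfg_hash=h)

    stage = "load_inputs"
    try:
        adata, cn, genes, gene_sets, promoters, truth = load_inputs(cfg)

        stage = "qc"
        th = qc.QCThresholds(**cfg.qc)
        filtered, report = qc.qc_filter(adata, th)
        write_tsv(report.to_frame(), outdir / "qc_report.tsv", index=False, **stamp)

        stage = "clone_cn"
        profiles = clone_median_profiles(cn)
        gene_coords = genes.dropna(subset=["chrom"]) if genes is not None else None
        if gene_coords is None:
            raise ValueError("gene annotation is required")
        gene_map = map_genes_to_bins(gene_coords[["chrom", "start", "end"]], cn.bins)
        write_tsv(profiles.median_cn, outdir / "clone_profiles.tsv", **stamp)
        write_tsv(gene_map.table, outdir / "gene_bin_map.tsv", **stamp)

        stage = "clone_assign"
        ap = AssignmentParams(**cfg.assignment, seed=cfg.seed)
        sel_genes = select_assignment_genes(cn, profiles, gene_map, ap)
        human = filtered[:, [g for g in filtered.var_names if g in set(gene_coords.index)]]
        assignment = assign_clones(human, profiles, sel_genes, ap, gene_map)
        conc_table, conc_r = proportion_concordance(
            assignment, cn, filtered.obs["sample"] if "sample" in filtered.obs else
            pd.Series(index=filtered.obs_names, dtype=object))
        out_assign = pd.DataFrame(
            {"clone": assignment.assignments,
             "max_posterior": assignment.posterior.max(1)})
        write_tsv(out_assign, outdir / "assignments.tsv", **stamp)
        conc_table["pearson_r"] = conc_r
        write_tsv(conc_table, outdir / "concordance.tsv", index=False, **stamp)

        stage = "contrasts"
        meta = filtered.obs
        contrasts = select_contrast_clones(
            assignment.assignments, meta, min_cells=cfg.min_cells_per_contrast)
        de_cfg = cfg.de
        de_tables = {}
        for c in contrasts:
            key = f"{c['cond_a']}{c['clone_a']}_vs_{c['cond_b']}{c['clone_b']}_X{c['passage']}"
            stage = f"de:{key}"
            tab = _contrast_de(filtered, assignment.assignments, meta, c, de_cfg)
            de_tables[(c["passage"], c["cond_a"], c["cond_b"])] = (c, tab)
            write_tsv(tab, outdir / f"de_{key}.tsv", **stamp)

            stage = f"cistrans:{key}"
            sig = tab[(tab["fdr"] < de_cfg["de_fdr"])
                      & (tab["logFC"].abs() > de_cfg["de_lfc"])]
            if len(sig):
                calls = cis_trans.classify_cis_trans(
                    sig, gene_map, profiles, c["clone_a"], c["clone_b"])
                write_tsv(calls, outdir / f"cistrans_{key}.tsv", **stamp)
                props = cis_trans.summarize_proportions(calls)
                write_tsv(props, outdir / f"proportions_{key}.tsv", **stamp)

        stage = "dynamics"
        for passage in sorted({p for p, *_ in de_tables}):
            rx_unrx = de_tables.get((passage, "Rx", "UnRx"))
            rx_rxh = de_tables.get((passage, "Rx", "RxH"))
            if rx_unrx and rx_rxh:
                stable = dynamics.stable_response_genes(
                    rx_unrx[1], rx_rxh[1], de_fdr=de_cfg["de_fdr"],
                    de_lfc=de_cfg["de_lfc"], stable_fdr=de_cfg["stable_fdr"])
                diverged = dynamics.holiday_divergence(
                    rx_rxh[1], rx_unrx[1], de_fdr=de_cfg["de_fdr"],
                    de_lfc=de_cfg["de_lfc"])
                write_tsv(pd.concat([stable, diverged]),
                          outdir / f"dynamics_X{passage}.tsv", **stamp)

        stage = "enrichment"
        if gene_sets is not None:
            for (passage, ca, cb), (c, tab) in de_tables.items():
                if (ca, cb) != ("Rx", "UnRx"):
                    continue
                sig = tab[(tab["fdr"] < de_cfg["de_fdr"])
                          & (tab["logFC"].abs() >= 0.25)]
                if len(sig) < 10:
                    continue
                res = enrichment.preranked_gsea(
                    sig["logFC"], gene_sets, n_perm=cfg.gsea.get("n_perm", 200),
                    seed=cfg.seed)
                write_tsv(res, outdir / f"gsea_RxUnRx_X{passage}.tsv", **stamp)

        stage = "trajectory"
        traj_cells = filtered
        est = trajectory.LineagePseudotime(
            random_state=cfg.seed, **cfg.trajectory)
        lin = est.fit_predict(traj_cells)
        pt_long = lin.pseudotime.stack().rename("pseudotime").reset_index()
        pt_long.columns = ["cell_id", "lineage", "pseudotime"]
        pt_long["weight"] = [
            lin.weights.loc[r.cell_id, r.lineage] for r in pt_long.itertuples()
        ]
        write_tsv(pt_long, outdir / "pseudotime.tsv", index=False, **stamp)

        norm = trajectory.normalize_counts(traj_cells)
        usable = sum(
            (lin.weights.to_numpy().argmax(1) == li).sum() >= 20
            for li in range(lin.n_lineages)
        )
        if usable < 2:
            # a single (usable) lineage admits no between-lineage test
            log.info("only %d usable lineage(s); skipping lineage gene tests", usable)
            return outdir
        tests = trajectory.lineage_gene_tests(
            norm, lin, n_perm=cfg.trajectory_n_perm, seed=cfg.seed)
        write_tsv(tests, outdir / "lineage_tests.tsv", **stamp)
        # a gene is trajectory-significant when its pattern differs between
        # lineages AND its endpoints or early segments differ; when the
        # BH-adjusted rule is starved by permutation granularity, fall back
        # to the top-N genes by pattern statistic among raw-significant ones
        sig_genes = tests.index[
            (tests["pattern_p_adj"] < 0.05)
            & ((tests["end_p_adj"] < 0.05) | (tests["early_p_adj"] < 0.05))
        ]
        if len(sig_genes) < 10:
            raw = tests[
                (tests["pattern_p"] < 0.05)
                & ((tests["end_p"] < 0.05) | (tests["early_p"] < 0.05))
            ]
            sig_genes = raw.nlargest(cfg.trajectory_top_n, "pattern_stat").index
        module_status = None
        if len(sig_genes) >= 10:
            curves = trajectory.smoothed_lineage_curves(norm, lin, list(sig_genes))
            modules = trajectory.cluster_gene_modules(curves, seed=cfg.seed)
            named = modules.labels.map(lambda m: f"M{m + 1}" if m >= 0 else "dropped")
            write_tsv(named.to_frame("module"), outdir / "modules.tsv", **stamp)
            write_tsv(modules.curves, outdir / "module_curves.tsv", **stamp)

            stage = "chromatin"
            if promoters is not None:
                ratios = chrom_mod.chip_input_rpm(promoters)
                controls = [g for g in ratios.index if str(g).startswith("CTRL")]
                module_genes = {
                    m: [g for g in gs if g in ratios.index]
                    for m, gs in modules.modules.items()
                }
                module_genes = {m: gs for m, gs in module_genes.items()
                                if len(gs) >= chrom_mod.MIN_MODULE}
                if module_genes and len(controls) >= chrom_mod.MIN_CONTROL:
                    status = chrom_mod.classify_all_modules(
                        ratios, module_genes, controls,
                        alpha=cfg.chromatin.get("alpha", 0.05))
                    write_tsv(status, outdir / "module_status.tsv", **stamp)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return outdir
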