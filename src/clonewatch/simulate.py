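"""Ground-truth simulator for clone-resolved PDX drug-response time series.

The generator emulates the study design this package analyzes: a
polyclonal tumor serially passaged under three arms — never treated
(UnRx), continuously drug treated (Rx), and treated-then-withdrawn
(RxH) — with joint single-cell measurements:

* integer copy-number profiles of each clone on fixed 500-kb-style
  genomic bins, drawn as segmental changes around diploid ploidy;
* clone prevalences evolving by deterministic selection (per-passage
  fitness multipliers, inverted under treatment for designated resistant
  clones so a minor clone can sweep), with cells drawn multinomially;
* UMI counts whose negative-binomial means scale with gene dosage
  ``(cn/2)**delta`` — a small fraction of genes is anti-correlated
  (delta <= 0) — times a condition factor encoding treatment-induced /
  repressed programs that are either reversible or fixed on holiday;
* mouse-cell and low-quality-cell contamination for the QC stage;
* promoter ChIP read counts with Active / Bivalent / Repressed
  enrichment structure for the chromatin stage.

Everything is deterministic given ``SimulationParams.seed``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from anndata import AnnData

from .clone_cn import CNMatrix

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "PromoterCountTable",
    "simulate_truth",
    "simulate_cells",
    "simulate_chip_counts",
    "simulate_dataset",
    "simulate_linear_trajectory",
    "simulate_branching_trajectory",
]

BIN_SIZE = 500_000
PROGRAM_LABELS = (
    "neutral",
    "induced_fixed",
    "induced_reversible",
    "repressed_fixed",
    "repressed_reversible",
    "anticorrelated",
)
#: promoter chromatin class planted per gene program
CHROMATIN_MAP = {
    "neutral": "repressed",
    "induced_fixed": "active",
    "induced_reversible": "bivalent",
    "repressed_fixed": "repressed",
    "repressed_reversible": "bivalent",
    "anticorrelated": "repressed",
}
#: ChIP/input enrichment ratios per (class, mark)
CHIP_ENRICHMENT = {
    "active": {"H3K4me3": 5.0, "H3K27me3": 1.0},
    "bivalent": {"H3K4me3": 5.0, "H3K27me3": 5.0},
    "repressed": {"H3K4me3": 1.0, "H3K27me3": 5.0},
}


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults define the study-like regime.

    ``fitness`` holds the per-passage growth multiplier s of each clone
    under no treatment; ``rx_fitness`` the multipliers applied while on
    drug.  By default the last clone is the designated resistant clone:
    a minor population untreated, strongly favored under treatment, so a
    clonal sweep develops over the treated passages.
    """

    n_bins: int = 200
    n_clones: int = 3
    genes_per_bin: int = 8
    n_passages: int = 4
    conditions: tuple = ("UnRx", "Rx", "RxH")
    cells_per_sample: int = 400
    fitness: dict | None = None
    rx_fitness: dict | None = None
    initial_prevalence: dict | None = None
    dosage_exponent: float = 1.0
    frac_anticorrelated: float = 0.03
    nb_dispersion: float = 2.0
    program_sizes: dict = field(
        default_factory=lambda: {
            "induced_fixed": 50,
            "induced_reversible": 50,
            "repressed_fixed": 50,
            "repressed_reversible": 50,
        }
    )
    induced_fold: float = 2.0
    repressed_fold: float = 0.5
    frac_mouse_cells: float = 0.05
    frac_lowqc_cells: float = 0.05
    frac_doublets: float = 0.02
    flip_rate: float = 0.01
    frac_boundary_genes: float = 0.10
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    n_mouse_genes: int = 50
    base_mean_log_mu: float = 0.7
    base_mean_log_sigma: float = 0.8
    library_log_sigma: float = 0.25
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_bins * self.genes_per_bin

    @property
    def clone_labels(self) -> list[str]:
        letters = string.ascii_uppercase
        return [letters[i % 26] + ("" if i < 26 else str(i // 26)) for i in range(self.n_clones)]

    def validate(self) -> None:
        if self.n_clones < 2:
            raise ValueError("need >=2 clones")
        for name in (
            "frac_anticorrelated",
            "frac_mouse_cells",
            "frac_lowqc_cells",
            "frac_doublets",
            "flip_rate",
            "frac_boundary_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for fmap in (self.fitness, self.rx_fitness):
            if fmap is not None:
                vals = np.array(list(fmap.values()), dtype=float)
                if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                    raise ValueError("fitness values must be finite and >= 0")
                if np.all(vals == 0):
                    raise ValueError("degenerate fitness: all zero")

    def resolved_fitness(self) -> tuple[dict, dict]:
        labels = self.clone_labels
        fit = dict(self.fitness) if self.fitness else {c: 1.0 for c in labels}
        if self.rx_fitness:
            rx = dict(self.rx_fitness)
        else:
            # fitness landscape inversion: the last clone is resistant
            rx = {c: 0.7 for c in labels}
            rx[labels[-1]] = 2.0
        return fit, rx

    def resolved_initial_prevalence(self) -> dict:
        labels = self.clone_labels
        if self.initial_prevalence:
            p = np.array([self.initial_prevalence[c] for c in labels], dtype=float)
        else:
            # resistant clone starts minor
            p = np.full(self.n_clones, 1.0)
            p[-1] = 0.25
        p = p / p.sum()
        return dict(zip(labels, p))


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for oracle-style testing."""

    params: SimulationParams
    bins: pd.DataFrame
    clone_cn: pd.DataFrame  # clones x bins, int in {0..8}
    prevalence: pd.DataFrame  # samples x clones, deterministic update
    sample_meta: pd.DataFrame  # sample -> (condition, passage)
    genes: pd.DataFrame  # gene_id -> chrom/start/end/strand/bin/program/...
    base_mean: pd.Series
    cell_truth: pd.DataFrame

    @property
    def gene_program(self) -> pd.Series:
        return self.genes["program"]


@dataclass
class PromoterCountTable:
    """Promoter-level read counts for ChIP marks and input controls."""

    counts: pd.DataFrame  # gene x track columns, plus interval columns
    library_sizes: pd.Series  # track -> library size
    tracks: dict  # mark -> list of replicate column names


def _simulate_clone_profiles(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Segmental Markov profiles around ploidy 2, pairwise distinct."""
    n_bins, n_clones = params.n_bins, params.n_clones
    for _ in range(100):
        ancestor = np.full(n_bins, 2, dtype=int)
        pos = 0
        while pos < n_bins:  # ancestral segmental states
            seg = int(rng.geometric(0.08))
            ancestor[pos : pos + seg] = rng.choice([1, 2, 2, 2, 3])
            pos += seg
        profiles = np.tile(ancestor, (n_clones, 1))
        for k in range(n_clones):
            for _ev in range(4):
                start = int(rng.integers(0, n_bins))
                length = int(rng.geometric(0.12))
                delta = int(rng.choice([-2, -1, 1, 1, 2]))
                profiles[k, start : start + length] += delta
        profiles = np.clip(profiles, 0, 8)
        distinct = all(
            np.any(profiles[i] != profiles[j])
            for i in range(n_clones)
            for j in range(i + 1, n_clones)
        )
        if distinct:
            return profiles
    raise RuntimeError("could not draw pairwise-distinct clone profiles")


def _make_bins(n_bins: int) -> pd.DataFrame:
    """Lay bins on chr1..chrN, ~40 bins per chromosome, 500 kb each."""
    per_chrom = 40
    rows = []
    for i in range(n_bins):
        chrom = f"chr{i // per_chrom + 1}"
        off = i % per_chrom
        rows.append((chrom, off * BIN_SIZE, (off + 1) * BIN_SIZE))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _place_genes(params: SimulationParams, bins: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes_per_bin genes in each bin; a fraction straddles the
    next bin boundary (majority of the body stays in its own bin)."""
    rows = []
    n_bins = len(bins)
    gid = 0
    for b in range(n_bins):
        chrom, start, end = bins.iloc[b]
        for _ in range(params.genes_per_bin):
            gid += 1
            name = f"G{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            straddle = (
                rng.random() < params.frac_boundary_genes
                and b + 1 < n_bins
                and bins.iloc[b + 1]["chrom"] == chrom
            )
            if straddle:
                gs = end - 30_000  # 30 kb inside own bin, 20 kb beyond
                ge = end + 20_000
            else:
                gs = start + int(rng.integers(0, BIN_SIZE - 60_000))
                ge = gs + int(rng.integers(2_000, 50_000))
            rows.append((name, chrom, gs, ge, strand, b, straddle))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "bin", "spans_boundary"]
    ).set_index("gene_id")


def simulate_truth(params: SimulationParams) -> SyntheticTruth:
    """Draw the full ground truth: clone genomes, prevalence trajectories,
    gene programs, per-cell clone/condition labels.

    The prevalence chain is the deterministic selection update
    ``p'_k = p_k * s_k / sum_j p_j * s_j`` per passage, with the fitness
    map chosen by arm (UnRx fitness off drug, rx_fitness on drug; the
    holiday arm continues the treated chain for one passage off drug).
    Cells are then drawn multinomially from the chain's prevalences.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = params.clone_labels
    bins = _make_bins(params.n_bins)
    profiles = _simulate_clone_profiles(params, rng)
    clone_cn = pd.DataFrame(profiles, index=labels)

    fit_unrx, fit_rx = params.resolved_fitness()
    f_u = np.array([fit_unrx[c] for c in labels], dtype=float)
    f_r = np.array([fit_rx[c] for c in labels], dtype=float)
    p0 = np.array(list(params.resolved_initial_prevalence().values()), dtype=float)

    def step(p, f):
        q = p * f
        s = q.sum()
        if s == 0:
            raise ValueError("degenerate fitness: prevalence mass vanished")
        return q / s

    prev_rows, meta_rows = [], []
    p_unrx, p_rx = p0.copy(), p0.copy()
    for x in range(1, params.n_passages + 1):
        p_unrx = step(p_unrx, f_u)
        if "UnRx" in params.conditions:
            prev_rows.append((f"UnRx_X{x}", *p_unrx))
            meta_rows.append((f"UnRx_X{x}", "UnRx", x))
        p_rx_prev = p_rx.copy()
        p_rx = step(p_rx, f_r)
        if "Rx" in params.conditions:
            prev_rows.append((f"Rx_X{x}", *p_rx))
            meta_rows.append((f"Rx_X{x}", "Rx", x))
        if "RxH" in params.conditions and x >= 2:
            # holiday: treated chain up to x-1, then one passage off drug
            p_rxh = step(p_rx_prev, f_u)
            prev_rows.append((f"RxH_X{x}", *p_rxh))
            meta_rows.append((f"RxH_X{x}", "RxH", x))
    prevalence = pd.DataFrame(
        [r[1:] for r in prev_rows], index=[r[0] for r in prev_rows], columns=labels
    )
    sample_meta = pd.DataFrame(
        [m[1:] for m in meta_rows], index=[m[0] for m in meta_rows],
        columns=["condition", "passage"],
    )

    genes = _place_genes(params, bins, rng)
    n_genes = len(genes)
    program = np.array(["neutral"] * n_genes, dtype=object)
    perm = rng.permutation(n_genes)
    cursor = 0
    n_anti = int(round(params.frac_anticorrelated * n_genes))
    anti_idx = perm[cursor : cursor + n_anti]
    program[anti_idx] = "anticorrelated"
    cursor += n_anti
    for label, size in params.program_sizes.items():
        if label not in PROGRAM_LABELS:
            raise ValueError(f"unknown program label {label!r}")
        program[perm[cursor : cursor + size]] = label
        cursor += size
    genes["program"] = program
    delta = np.full(n_genes, params.dosage_exponent)
    delta[anti_idx] = -1.0
    genes["dosage_exponent"] = delta
    chrom_class = genes["program"].map(CHROMATIN_MAP).to_numpy(dtype=object)
    neutral = genes["program"].to_numpy() == "neutral"
    chrom_class[neutral] = rng.choice(
        ["active", "bivalent", "repressed"], size=int(neutral.sum()), p=[0.5, 0.2, 0.3]
    )
    genes["chromatin_class"] = chrom_class

    base_mean = pd.Series(
        rng.lognormal(params.base_mean_log_mu, params.base_mean_log_sigma, n_genes),
        index=genes.index,
        name="base_mean",
    )

    # per-cell truth: clone draws + contamination flags
    cell_rows = []
    for sample in prevalence.index:
        cond, x = sample_meta.loc[sample]
        counts = rng.multinomial(params.cells_per_sample, prevalence.loc[sample].to_numpy())
        clones = np.repeat(labels, counts)
        clones = rng.permutation(clones)
        n = len(clones)
        is_mouse = rng.random(n) < params.frac_mouse_cells
        is_lowqc = (~is_mouse) & (rng.random(n) < params.frac_lowqc_cells)
        is_doublet = (~is_mouse) & (rng.random(n) < params.frac_doublets)
        for i in range(n):
            cell_rows.append(
                (f"{sample}_c{i:04d}", sample, cond, x, clones[i],
                 bool(is_mouse[i]), bool(is_lowqc[i]), bool(is_doublet[i]))
            )
    cell_truth = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "sample", "condition", "passage", "clone",
                 "is_mouse", "is_lowqc", "is_doublet"],
    ).set_index("cell_id")

    return SyntheticTruth(
        params=params, bins=bins, clone_cn=clone_cn, prevalence=prevalence,
        sample_meta=sample_meta, genes=genes, base_mean=base_mean,
        cell_truth=cell_truth,
    )


def _dosage_factor(cn: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """(cn/2)**delta with bounded edge cases: dosage-following genes keep
    a small residual at copy 0 (0.1x); anti-correlated genes (delta <= 0)
    clamp copy at 1 so a deletion cannot blow expression up."""
    cn = np.asarray(cn, dtype=float)
    delta = np.asarray(delta, dtype=float)
    eff = np.where(delta >= 0, np.maximum(cn, 0.2), np.maximum(cn, 1.0))
    return (eff / 2.0) ** delta


def _condition_factor(program: np.ndarray, condition: str, params: SimulationParams) -> np.ndarray:
    """tau_g(condition): program fold applied under Rx; under RxH only
    the fixed programs keep it (reversible programs return to baseline)."""
    tau = np.ones(len(program))
    if condition == "Rx":
        tau[np.isin(program, ["induced_fixed", "induced_reversible"])] = params.induced_fold
        tau[np.isin(program, ["repressed_fixed", "repressed_reversible"])] = params.repressed_fold
    elif condition == "RxH":
        tau[program == "induced_fixed"] = params.induced_fold
        tau[program == "repressed_fixed"] = params.repressed_fold
    return tau


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with Var = mu + mu^2/size, size = dispersion."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def expected_counts(truth: SyntheticTruth, condition: str, clone: str) -> pd.Series:
    """Generative NB mean per gene for a unit-library cell of ``clone``
    under ``condition`` (no flip noise) — the oracle for mean checks."""
    params = truth.params
    genes = truth.genes
    cn = truth.clone_cn.loc[clone].to_numpy()[genes["bin"].to_numpy()]
    dosage = _dosage_factor(cn, genes["dosage_exponent"].to_numpy())
    tau = _condition_factor(genes["program"].to_numpy(), condition, params)
    return pd.Series(truth.base_mean.to_numpy() * dosage * tau, index=genes.index)


def simulate_cells(truth: SyntheticTruth, params: SimulationParams | None = None
                   ) -> tuple[CNMatrix, AnnData]:
    """Emit the two single-cell modalities for every cell in the truth.

    Returns the per-cell copy-number matrix (clone profile plus per-bin
    flip noise) and an AnnData of UMI counts over human dosage genes,
    mitochondrial/ribosomal features, and a disjoint mouse feature
    namespace (``mm_*``).  Mouse cells emit counts predominantly on the
    mouse features; low-QC cells have inflated mitochondrial fraction
    and depressed gene detection.
    """
    params = params or truth.params
    if (truth.base_mean <= 0).any():
        bad = truth.base_mean.index[truth.base_mean <= 0][:3]
        raise ValueError(f"zero/negative base_mean for genes {list(bad)}")
    rng = np.random.default_rng(params.seed + 1)
    cells = truth.cell_truth
    labels = list(truth.clone_cn.index)
    n_cells = len(cells)
    n_bins = params.n_bins

    # --- per-cell CN with flip noise (human, non-mouse cells only keep
    # their clone profile; mouse cells get a flat diploid placeholder) ---
    clone_idx = np.array([labels.index(c) for c in cells["clone"]])
    copy = truth.clone_cn.to_numpy()[clone_idx].copy()
    flips = rng.random((n_cells, n_bins)) < params.flip_rate
    signs = rng.choice([-1, 1], size=(n_cells, n_bins))
    copy = np.clip(copy + flips * signs, 0, 8)
    cn = CNMatrix(
        bins=truth.bins,
        copy=pd.DataFrame(copy, index=cells.index, columns=range(n_bins)),
        clone=cells["clone"].copy(),
    )

    # --- expression features ---
    genes = truth.genes
    mito = [f"MT-{i}" for i in range(1, params.n_mito_genes + 1)]
    ribo = [f"RPS{i}" if i % 2 else f"RPL{i}" for i in range(1, params.n_ribo_genes + 1)]
    mouse = [f"mm_Gene{i}" for i in range(1, params.n_mouse_genes + 1)]
    var_names = list(genes.index) + mito + ribo + mouse
    n_dosage = len(genes)

    base = truth.base_mean.to_numpy()
    total_base = base.sum()
    # mito ~5 % and ribo ~20 % of a normal cell's counts
    mito_base = np.full(len(mito), 0.05 * total_base / max(len(mito), 1) / 0.75)
    ribo_base = np.full(len(ribo), 0.20 * total_base / max(len(ribo), 1) / 0.75)
    mouse_base = np.full(len(mouse), total_base / max(len(mouse), 1))

    gene_bin = genes["bin"].to_numpy()
    delta = genes["dosage_exponent"].to_numpy()
    program = genes["program"].to_numpy()

    lib = rng.lognormal(0.0, params.library_log_sigma, n_cells)
    X = np.zeros((n_cells, len(var_names)), dtype=np.int64)
    conditions = cells["condition"].to_numpy()
    is_mouse = cells["is_mouse"].to_numpy()
    is_lowqc = cells["is_lowqc"].to_numpy()

    tau_by_cond = {c: _condition_factor(program, c, params) for c in np.unique(conditions)}
    for i in range(n_cells):
        if is_mouse[i]:
            mouse_mean = lib[i] * mouse_base
            X[i, n_dosage + len(mito) + len(ribo):] = _nb_draw(rng, mouse_mean, params.nb_dispersion)
            # trace human counts well below the mouse total
            stray = lib[i] * 0.02 * base
            X[i, :n_dosage] = _nb_draw(rng, stray, params.nb_dispersion)
            continue
        cn_g = copy[i, gene_bin]
        dosage = _dosage_factor(cn_g, delta)
        mean_g = lib[i] * base * dosage * tau_by_cond[conditions[i]]
        mean_m = lib[i] * mito_base
        mean_r = lib[i] * ribo_base
        if is_lowqc[i]:
            mean_m = mean_m * 20.0
            mean_g = mean_g * 0.25  # depressed gene detection
            mean_r = mean_r * 0.25
        X[i, :n_dosage] = _nb_draw(rng, mean_g, params.nb_dispersion)
        X[i, n_dosage : n_dosage + len(mito)] = _nb_draw(rng, mean_m, params.nb_dispersion)
        X[i, n_dosage + len(mito) : n_dosage + len(mito) + len(ribo)] = _nb_draw(
            rng, mean_r, params.nb_dispersion
        )

    var = pd.DataFrame(index=pd.Index(var_names, name="gene_id"))
    var["feature_class"] = (
        ["dosage"] * n_dosage + ["mito"] * len(mito) + ["ribo"] * len(ribo) + ["mouse"] * len(mouse)
    )
    for col in ("chrom", "start", "end", "strand"):
        var[col] = genes[col].reindex(var.index)
    obs = cells.copy()
    obs["clone"] = obs["clone"].astype(str)
    adata = AnnData(X=X, obs=obs, var=var)
    return cn, adata


def simulate_chip_counts(truth: SyntheticTruth, params: SimulationParams | None = None,
                         *, base_rate: float = 20.0, n_control: int = 500,
                         library_size: float = 1e6) -> PromoterCountTable:
    """Poisson promoter counts for H3K4me3 / H3K27me3 / input (2 reps each).

    Every gene carries its planted chromatin class (program genes via
    the program->class map, neutral genes a drawn class); a repressed
    control block of ``n_control`` extra promoters (``CTRL*``) is
    appended with the repressed class's generative parameters.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 2)
    genes = truth.genes
    names = list(genes.index) + [f"CTRL{i:04d}" for i in range(1, n_control + 1)]
    classes = list(genes["chromatin_class"]) + ["repressed"] * n_control

    tracks = {
        "H3K4me3": ["H3K4me3_1", "H3K4me3_2"],
        "H3K27me3": ["H3K27me3_1", "H3K27me3_2"],
        "input": ["input_1", "input_2"],
    }
    lib = {}
    for mark, cols in tracks.items():
        for j, col in enumerate(cols):
            lib[col] = library_size * (1.0 + 0.1 * j)

    rows = {}
    for col in [c for cols in tracks.values() for c in cols]:
        mark = col.rsplit("_", 1)[0]
        scale = lib[col] / library_size
        lam = np.array(
            [
                base_rate * (1.0 if mark == "input" else CHIP_ENRICHMENT[cls][mark]) * scale
                for cls in classes
            ]
        )
        rows[col] = rng.poisson(lam)
    counts = pd.DataFrame(rows, index=pd.Index(names, name="gene"))
    counts.insert(0, "chrom", "chr1")
    counts.insert(1, "start", np.arange(len(names)) * 10_000)
    counts.insert(2, "end", np.arange(len(names)) * 10_000 + 2_000)
    counts["chromatin_class"] = classes
    return PromoterCountTable(
        counts=counts, library_sizes=pd.Series(lib), tracks=tracks
    )


def simulate_dataset(params: SimulationParams | None = None, seed: int | None = None
                     ) -> tuple[SyntheticTruth, CNMatrix, AnnData]:
    """Convenience: truth + both single-cell modalities in one call."""
    params = params or SimulationParams()
    if seed is not None:
        params = replace(params, seed=seed)
    truth = simulate_truth(params)
    cn, adata = simulate_cells(truth, params)
    return truth, cn, adata


# ---------------------------------------------------------------------------
# focused trajectory fixtures (latent-time ground truth)
# ---------------------------------------------------------------------------

def simulate_linear_trajectory(n_cells: int = 600, n_genes: int = 50,
                               depth: float = 2000.0, dispersion: float = 5.0,
                               seed: int = 0) -> tuple[AnnData, np.ndarray]:
    """Cells along a single latent time t in [0, 1]; half the genes ramp
    up, half ramp down, NB noise.  Returns (AnnData, latent time)."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(n_cells))
    up = np.arange(n_genes) % 2 == 0
    lo, hi = 1.0, 8.0
    means = np.where(up[None, :], lo + (hi - lo) * t[:, None], hi - (hi - lo) * t[:, None])
    means = means * depth / means.sum(1, keepdims=True) * n_genes / n_genes
    X = _nb_draw(rng, means, dispersion)
    obs = pd.DataFrame(
        {
            "condition": np.where(t < 0.34, "UnRx", np.where(t < 0.67, "Rx", "RxH")),
            "passage": (1 + (t * 6).astype(int)).clip(1, 6),
        },
        index=[f"cell{i:04d}" for i in range(n_cells)],
    )
    adata = AnnData(X=X, obs=obs,
                    var=pd.DataFrame(index=[f"T{i:03d}" for i in range(n_genes)]))
    return adata, t


def simulate_branching_trajectory(n_cells: int = 900, n_genes: int = 60,
                                  dispersion: float = 5.0, seed: int = 0
                                  ) -> tuple[AnnData, np.ndarray, np.ndarray]:
    """Shared trunk (t < 0.5) then two diverging programs.  Returns
    (AnnData, latent time, branch labels 0/1; trunk cells labeled -1)."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(n_cells))
    branch = np.where(t < 0.5, -1, rng.integers(0, 2, n_cells))
    third = n_genes // 3
    means = np.full((n_cells, n_genes), 3.0)
    ramp = np.clip((t - 0.5) * 2, 0, 1)
    # trunk genes ramp with t everywhere; branch genes diverge after the split
    means[:, :third] = 2.0 + 8.0 * t[:, None]
    mask0 = branch == 0
    mask1 = branch == 1
    means[np.ix_(mask0, np.arange(third, 2 * third))] += 8.0 * ramp[mask0][:, None]
    means[np.ix_(mask1, np.arange(2 * third, 3 * third))] += 8.0 * ramp[mask1][:, None]
    X = _nb_draw(rng, means, dispersion)
    obs = pd.DataFrame(
        {
            "condition": np.where(t < 0.5, "UnRx", np.where(branch == 0, "Rx", "RxH")),
            "passage": (1 + (t * 6).astype(int)).clip(1, 6),
        },
        index=[f"cell{i:04d}" for i in range(n_cells)],
    )
    adata = AnnData(X=X, obs=obs,
                    var=pd.DataFrame(index=[f"B{i:03d}" for i in range(n_genes)]))
    return adata, t, branch
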