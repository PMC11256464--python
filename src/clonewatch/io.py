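"""On-disk formats: MTX triplets, long-format CN tables, BED/GTF, GMT,
promoter counts, provenance-stamped TSV outputs, YAML configuration.

Conventions: chromosome names ``chr1..chrN``; 0-based half-open
coordinates internally (BED native; GTF's 1-based inclusive start is
converted on read); MatrixMarket coordinate integer for counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from anndata import AnnData

from . import __version__
from .clone_cn import CNMatrix
from .enrichment import GeneSetCollection
from .simulate import PromoterCountTable

__all__ = [
    "write_counts_mtx", "read_counts_mtx",
    "write_cn_long", "read_cn_long",
    "write_metadata", "read_metadata",
    "read_bed", "write_bed", "read_gtf_genes",
    "read_gmt", "write_gmt",
    "write_promoter_counts", "read_promoter_counts",
    "write_tsv", "PipelineConfig", "load_config", "config_hash",
]


# --- counts (MTX triplet + barcodes + features) ----------------------------

def write_counts_mtx(adata: AnnData, outdir) -> Path:
    """Write genes x cells MatrixMarket triplet plus barcodes.tsv and
    features.tsv (10x-style layout, uncompressed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame({"gene_id": adata.var_names})
    if "feature_class" in adata.var:
        feats["feature_class"] = adata.var["feature_class"].to_numpy()
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    return outdir


def read_counts_mtx(indir) -> AnnData:
    """Read the triplet layout back into an AnnData (cells x genes)."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"MTX dimensions {mat.shape} do not match features x barcodes "
            f"({len(features)}, {len(barcodes)})"
        )
    gene_ids = features[0].astype(str)
    if gene_ids.duplicated().any():
        raise ValueError("duplicate gene ids in features.tsv")
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if features.shape[1] > 1:
        var["feature_class"] = features[1].to_numpy()
    adata = AnnData(X=sp.csr_matrix(mat.T), var=var,
                    obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")))
    return adata


# --- copy number (long TSV) ------------------------------------------------

def write_cn_long(cn: CNMatrix, path) -> Path:
    path = Path(path)
    bins = cn.bins
    rows = []
    copy = cn.copy
    long = copy.stack()
    long.index.names = ["cell_id", "bin"]
    df = long.reset_index(name="copy")
    df["chrom"] = bins["chrom"].to_numpy()[df["bin"].to_numpy(dtype=int)]
    df["start"] = bins["start"].to_numpy()[df["bin"].to_numpy(dtype=int)]
    df["end"] = bins["end"].to_numpy()[df["bin"].to_numpy(dtype=int)]
    df["clone"] = cn.clone.reindex(df["cell_id"]).to_numpy()
    df[["cell_id", "chrom", "start", "end", "copy", "clone"]].to_csv(
        path, sep="\t", index=False
    )
    return path


def read_cn_long(path) -> CNMatrix:
    df = pd.read_csv(path, sep="\t")
    bins = (
        df[["chrom", "start", "end"]]
        .drop_duplicates()
        .sort_values(["chrom", "start"], key=lambda s: _chrom_key(s) if s.name == "chrom" else s)
        .reset_index(drop=True)
    )
    key = bins["chrom"] + ":" + bins["start"].astype(str)
    bin_idx = pd.Series(range(len(bins)), index=key)
    df["bin"] = bin_idx[(df["chrom"] + ":" + df["start"].astype(str))].to_numpy()
    copy = df.pivot_table(index="cell_id", columns="bin", values="copy", aggfunc="first")
    copy = copy.sort_index(axis=1)
    copy.columns = range(copy.shape[1])
    clone = df.drop_duplicates("cell_id").set_index("cell_id")["clone"]
    return CNMatrix(bins=bins, copy=copy.astype(int), clone=clone.reindex(copy.index))


def _chrom_key(s: pd.Series) -> pd.Series:
    def k(c):
        c = str(c).removeprefix("chr")
        return int(c) if c.isdigit() else 1000 + ord(c[0])
    return s.map(k)


# --- metadata / annotation -------------------------------------------------

def write_metadata(obs: pd.DataFrame, path) -> Path:
    obs.to_csv(path, sep="\t", index=True, index_label="cell_id")
    return Path(path)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open): chrom start end name [score strand]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"][: df.shape[1]]
    df.columns = cols
    if "gene_id" in df:
        df = df.set_index("gene_id")
    return df


def write_bed(genes: pd.DataFrame, path) -> Path:
    out = genes.reset_index()
    name_col = out.columns[0]
    cols = ["chrom", "start", "end", name_col]
    if "strand" in out:
        out["score"] = 0
        cols += ["score", "strand"]
    out[cols].to_csv(path, sep="\t", index=False, header=False)
    return Path(path)


def read_gtf_genes(path) -> pd.DataFrame:
    """Minimal GTF reader: gene features only; 1-based inclusive start is
    converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            rows.append((attrs.get("gene_id", f"{f[0]}:{f[3]}"), f[0], int(f[3]) - 1,
                         int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]
                        ).set_index("gene_id")


# --- gene sets (GMT) -------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets)


def write_gmt(sets: GeneSetCollection | dict, path, description: str = "clonewatch") -> Path:
    items = sets.items() if hasattr(sets, "items") else sets
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, description, *genes]) + "\n")
    return Path(path)


# --- promoter counts -------------------------------------------------------

def write_promoter_counts(table: PromoterCountTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        libs = ",".join(f"{k}={int(v)}" for k, v in table.library_sizes.items())
        fh.write(f"# library_sizes: {libs}\n")
        table.counts.to_csv(fh, sep="\t", index=True, index_label="gene")
    return path


def read_promoter_counts(path) -> PromoterCountTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# library_sizes:"):
            raise ValueError("promoter count table missing library_sizes header")
        libs = dict(kv.split("=") for kv in header.split(":", 1)[1].strip().split(","))
        libs = pd.Series({k: float(v) for k, v in libs.items()})
        counts = pd.read_csv(fh, sep="\t", index_col="gene")
    tracks = {}
    for col in counts.columns:
        if col in ("chrom", "start", "end", "chromatin_class"):
            continue
        mark = col.rsplit("_", 1)[0]
        tracks.setdefault(mark, []).append(col)
    return PromoterCountTable(counts=counts, library_sizes=libs, tracks=tracks)


# --- provenance-stamped TSV outputs ----------------------------------------

def write_tsv(df: pd.DataFrame, path, *, seed=None, cfg_hash=None, index=True) -> Path:
    """TSV with '#'-prefixed provenance header (version, seed, config
    hash — never a timestamp, so reruns are bit-identical)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# clonewatch {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


# --- configuration ---------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Paths may be absent when the run starts from the bundled simulator
    (``simulate: true``).  Parameter blocks are plain dicts forwarded to
    the stage constructors.
    """

    outdir: str = "clonewatch_out"
    seed: int = 0
    simulate: bool = True
    counts_dir: str | None = None
    cn_path: str | None = None
    metadata_path: str | None = None
    genes_bed: str | None = None
    gene_sets_gmt: str | None = None
    promoter_counts: str | None = None
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    assignment: dict = field(default_factory=dict)
    de: dict = field(default_factory=lambda: {"de_fdr": 0.01, "de_lfc": 0.5,
                                              "stable_fdr": 0.1})
    gsea: dict = field(default_factory=lambda: {"n_perm": 200})
    trajectory: dict = field(default_factory=dict)
    trajectory_n_perm: int = 200
    trajectory_top_n: int = 50
    chromatin: dict = field(default_factory=lambda: {"alpha": 0.05})
    min_cells_per_contrast: int = 100

    def validate(self) -> None:
        if not self.simulate:
            for name in ("counts_dir", "cn_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config path {name} missing or absent: {p}")

    def semantic_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d.pop("outdir")  # where outputs land is not semantically meaningful
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.semantic_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
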