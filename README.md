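# clonewatch

Clone-aware analysis of drug-induced transcriptomic reprogramming in
serially passaged tumor xenografts.

## The problem

In genomically unstable cancers such as triple-negative breast cancer,
copy-number aberrations (CNAs) are the dominant mutational mechanism,
and a single segmental gain or loss changes the dosage — and hence the
expression — of hundreds of genes at once. When a patient-derived
xenograft (PDX) is passaged for months under platinum treatment (Rx),
no treatment (UnRx), and treatment-then-holiday (RxH), two very
different resistance mechanisms compete inside the same tumor:

* **genomic**: a copy-number clone with high drug fitness sweeps the
  population, fixing a transcriptional state that barely reverts when
  the drug is withdrawn;
* **non-genomic**: transcriptional plasticity induces and represses
  programs that largely collapse back toward the untreated state on
  holiday, sometimes via new intermediate states.

Separating the two requires joint single-cell measurements: per-cell
copy-number profiles on fixed genomic bins (single-cell WGS) define the
clones, and scRNA-seq transcriptomes from the same populations are
assigned to those clones through the gene-dosage effect. `clonewatch`
implements that clone-aware pipeline end to end, for computational
biologists who have (or want to emulate) such paired time-series data.

## What it computes

| Stage | Model / rule |
|---|---|
| `simulate` | Ground-truth generator: clone CN profiles on 500-kb bins, prevalences evolving by per-passage fitness `p'_k ∝ p_k·s_k`, NB counts with mean `L_c·μ_g·(c_g/2)^δ·τ_g(condition)`, mouse/low-quality contamination, promoter ChIP counts |
| `qc` | Mouse rule (mouse-aligned counts > human-aligned, strict) plus four retention rules: ≥1000 detected genes, mito < 20 %, ribo < 60 %, totals within 3 MADs below the median |
| `clone_cn` | Per-clone median CN per bin (half-integers kept exact), per-bin-averaged Manhattan distances, gene → most-overlapping-bin map with boundary flags |
| `clone_assign` | EM mixture of multinomials with `π_kg ∝ μ_g·min(c_gk, 6)`: posterior clone per cell, gene filter at CN purity 0.6, concordance *r* between scRNA and scWGS clonal proportions |
| `dge` | Two-group NB Wald test with moment dispersions shrunk toward a mean-dispersion trend, size-factor offsets, BH FDR |
| `cis_trans` | Six trends: GainUp / LossDown (CN-correlated in-cis), GainDown / LossUp (anti-correlated in-cis), InTransUp / InTransDown; boundary-overlap diagnostic for anti-correlated genes |
| `dynamics` | Induced/repressed stable genes (DE at Rx vs UnRx, non-DE at Rx vs RxH) and holiday-diverged genes labeled toward / away from the untreated state by the sign rule |
| `enrichment` | Preranked GSEA (weighted KS running sum, gene-label permutation NES) and the four-way Rx/RxH pathway-change categories |
| `trajectory` | k-means + MST-over-centroids lineages, projection pseudotime, permutation pattern/end/early gene tests, cosine-distance gene modules |
| `chromatin` | 2-kb promoter windows, ChIP/input RPM ratios, ANOVA three-way Active / Bivalent / Repressed module classification against a 500-gene repressed control |

## Worked example

```python
from clonewatch.simulate import SimulationParams, simulate_dataset
from clonewatch.clone_cn import clone_median_profiles, map_genes_to_bins, manhattan_distance
from clonewatch.clone_assign import (AssignmentParams, select_assignment_genes,
                                     assign_clones, proportion_concordance)
from clonewatch.dge import de_test
from clonewatch.cis_trans import classify_cis_trans, summarize_proportions

params = SimulationParams(n_bins=80, n_clones=3, cells_per_sample=400,
                          n_passages=3, seed=0)
truth, cn, adata = simulate_dataset(params)

profiles = clone_median_profiles(cn)
gene_map = map_genes_to_bins(truth.genes[["chrom", "start", "end"]], cn.bins)
ap = AssignmentParams(seed=0)
genes = select_assignment_genes(cn, profiles, gene_map, ap)
result = assign_clones(adata[:, list(truth.genes.index)], profiles, genes, ap, gene_map)
table, r = proportion_concordance(result, cn, truth.cell_truth["sample"])
```

prints, step by step:

```
cells: 3200 features: 720 clones: ['A', 'B', 'C']
Manhattan distance A-B: 0.562
informative genes: 384
assignment accuracy: 0.989   clonal proportion r: 0.999
significant genes Rx vs UnRx (clone C): 198
{'in_cis': 0.0, 'InTransUp': 0.5, 'InTransDown': 0.5}
```

Reading the numbers: 3,200 simulated cells over three passages and three
arms; clones A and B differ by an average 0.56 copies per 500-kb bin;
384 genes sit in bins that are both pure and dosage-informative, and the
EM assigns 98.9 % of cells to their true clone, with scRNA-derived
clonal proportions matching the CN-side proportions at *r* = 0.999. The
final contrast compares the same clone C on and off drug, so every one
of the 198 significant genes is in-trans (no CN difference between a
clone and itself), split evenly between treatment-induced and
treatment-repressed — exactly the planted programs.

The same stages are available from a shell:

```bash
clonewatch simulate --outdir demo --seed 0
clonewatch qc --counts demo/counts --meta demo/metadata.tsv --outdir demo/qc --min-genes 400
clonewatch demo --outdir demo_run --seed 0   # full pipeline on synthetic data
```

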