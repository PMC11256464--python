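# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Synthetic study generator

The generator produces the joint data a serially passaged PDX drug
study yields: per-cell integer copy numbers on fixed bins, scRNA-seq
UMI counts from the same populations, and promoter-level ChIP counts.

**Clone genomes.** Each clone's profile is a segmental process around
diploid ploidy: an ancestral profile with geometric segment lengths and
states drawn near 2, plus four clone-specific segmental events of ±1–2
copies, clipped to {0..8}. Whole-genome duplication is deliberately not
simulated; profiles are guaranteed pairwise distinct. Bins are 500 kb,
laid 40 per chromosome (`chr1..chrN`), 0-based half-open.

**Prevalence dynamics.** Clone prevalences evolve by the deterministic
selection update `p'_k = p_k s_k / Σ_j p_j s_j` once per passage, with
one fitness map off drug and another on drug. The default maps invert
the landscape under treatment — the designated resistant clone is minor
untreated (initial prevalence weight 0.25 vs 1.0) and has fitness 2.0
on drug versus 0.7 for the others — so a clonal sweep develops over the
treated passages. The holiday arm continues the treated chain, then
takes one off-drug step. Cells are drawn multinomially from the
deterministic prevalences; drift does not feed back into the chain,
which keeps the update exactly testable against closed-form iteration.

**Expression.** A cell of clone *k* draws gene *g* as negative binomial
with mean `L_c · μ_g · d(c_gk, δ_g) · τ_g(condition)` and a shared
dispersion (`Var = μ + μ²/size`, size 2.0 by default — deliberately
noisy, matching droplet-level overdispersion). `μ_g` is log-normal
(log-mean 0.7, log-sd 0.8); `L_c` a log-normal library factor. The
dosage response is `d = (c/2)^δ` with two bounded edge cases: for
dosage-following genes (δ ≥ 0) copy 0 keeps a 0.1× residual, and for
anti-correlated genes (δ ≤ 0, 3 % of genes by default) the copy is
clamped at 1 from below so a homozygous deletion cannot blow expression
up by `(0.1)^-1`. `τ` encodes the treatment programs: induced genes
×2 on drug, repressed ×0.5, applied in the holiday arm only when the
program is *fixed*. 10 % of genes straddle a bin boundary (majority of
the body in the assigned bin) to exercise the boundary diagnostic.
Mouse cells emit counts on a disjoint `mm_*` feature namespace with
only trace human counts; low-quality cells get 20× mitochondrial means
and 4× depressed detection elsewhere. Per-cell CN adds independent
per-bin ±1 flip noise at rate 0.01 (no published per-cell noise rate
exists for this assay; the rate is a free parameter).

**Promoter ChIP.** Every gene carries a chromatin class — programs map
to classes (induced-fixed → active, reversible → bivalent,
repressed-fixed → repressed), neutral genes draw active/bivalent/
repressed at 0.5/0.2/0.3 — and Poisson counts are generated for
H3K4me3, H3K27me3 and input (2 replicates each) with ChIP/input ratios
(5, 1) active, (5, 5) bivalent, (1, 5) repressed, plus a 500-promoter
repressed control block.

**What the generator does not emulate.** Read-level artifacts, ambient
RNA, doublet transcriptome mixing (doublets are flags only), SNVs,
batch effects, and clone-by-condition interaction beyond the shared
program `τ`. Passing tests therefore demonstrate correctness of the
pipeline's logic and its statistical calibration under an idealized NB
world, not robustness to every real-data pathology.

## Quality control

Four retention rules (≥ `min_genes` detected genes, mito fraction
< 0.20, ribo fraction < 0.60, totals no more than 3 MADs below the
median total) after removing mouse cells by the strict-majority rule.
The MAD uses the 1.4826 Gaussian consistency constant (disablable).
Detected genes and totals are computed on human features only, after
mouse removal. The count-median is frozen into the output's `uns` so
re-filtering is idempotent. Mito/ribo features are recognized by
name prefix (`MT-`, `RPL|RPS`), configurable, since no authoritative
gene list is bundled.

## Clone assignment

The dosage model is a finite mixture of multinomials: cell counts over
selected genes are `Multinomial(N_c, π_k)` with `π_kg ∝ μ_g·d_gk`,
where `d_gk` is the clone median copy at the gene's bin clipped at the
saturation threshold 6, and copy 0 mapped to pseudo-dosage 0.1 (a
multinomial cannot carry exact zeros against a stray count). This is a
deliberate simplification of variational NB approaches: deterministic,
seconds-fast, with a closed-form minorize-maximize `μ` update whose
observed log-likelihood is provably non-decreasing (asserted by tests).
Three restarts from jittered initializations guard against local optima;
`μ` initializes from pooled empirical frequencies. Genes enter the model
only if every clone is ≥ 60 % modal at the gene's bin and the clone
modal copies are not all equal; cells with fewer than 25 counts over the
selected genes are dropped and reported rather than guessed.

## Differential expression

A self-contained two-group NB Wald test replaces quasi-likelihood
GLM machinery: size factors are per-cell totals over the median total
(used as offsets); per-gene dispersions come from moments on
size-factor-adjusted counts in each group, pooled, then shrunk toward a
20-bin mean-dispersion trend with a prior weight of 20
pseudo-observations; the Wald statistic is the difference of log group
means over its delta-method standard error. Genes must be nonzero in
≥ 1 % of either group's cells; a group mean of exactly 0 receives a
0.5 pseudo-count in the log2 fold change only. Null simulations at the
default conditions give empirical type-I error ≈ 0.05 at p < 0.05
(checked over 20 replicates). Gene lists can differ slightly from
quasi-likelihood F-test implementations, by design.

## Six-trend classification

A significance-filtered DE gene is in-cis when the clone median copy
numbers differ at its most-overlapping bin — medians compared exactly,
half-integers included, with an optional `min_delta` — and the sign
pair (ΔCN, logFC) yields GainUp/LossDown (correlated) or
GainDown/LossUp (anti-correlated); ΔCN = 0 gives InTransUp/Down.
The boundary diagnostic reports the fraction of anti-correlated genes
whose bodies straddle a bin boundary, the signature of segment-boundary
mis-assignment masquerading as counter-regulation.

## Gene dynamics

Stable response genes: DE at drug vs untreated (FDR < 0.01,
|logFC| > 0.5) and non-DE at drug vs holiday (FDR > 0.1); direction
labels them induced or repressed. The two FDR thresholds must satisfy
`stable_fdr > de_fdr` (enforced). Holiday-diverged genes: DE at drug vs
holiday, intersected with the full drug-vs-untreated table; same sign
= moved toward the untreated state, opposite sign (or a reference
logFC of exactly 0) = moved away. The intersection uses all tested
genes, not only DE ones, with a flag to restrict.

## Enrichment

Classic weighted KS running-sum preranked GSEA with weight p = 1, ties
broken by gene id. The null permutes gene labels (sample permutation is
unavailable downstream of per-clone DE); NES divides ES by the mean
|permuted ES| of the same sign, and the empirical p is computed within
the sign class with the +1 correction. The default input is the
DE-significant subset ranked by logFC; whole-transcriptome rankings are
a caller choice. Four-way pathway-change categories compare a treated
and a holiday result table at p < 0.05 per side.

## Trajectory

Normalization is `log1p(count/sf)` after dropping genes zero in
> 97.5 % of cells and mitochondrial features — a monotone,
self-contained substitute for regularized-NB residuals, adequate for
trajectory geometry. Highly variable genes (3000) by standardized
variance, PCA to 30 components, k-means with k = 8 (the clustering
resolution analogue), outlier clusters below 1 % of cells removed.
Lineages are root-to-leaf paths of the MST over cluster centroids in PC
space; the start cluster holds the most untreated cells from the
earliest passage. Pseudotime is the arc-length position of each cell's
orthogonal projection onto its lineage's piecewise-linear centroid
path. All lineages share one arc-length scale (the longest path) so
trunk cells land at the same pseudotime on every lineage that contains
them — without this, per-lineage normalization warps the shared trunk
and inflates between-lineage statistics for any time-varying gene.
Replacing simultaneous principal curves with these piecewise-linear
paths is the module's largest simplification: deterministic and
sufficient for monotone pseudotime recovery, but it will not smooth
strongly curved manifolds.

Between-lineage gene tests are permutation-based on smoothed curves
(20 pseudotime bins, linear interpolation to a 100-point grid, light
Gaussian smoothing): the pattern statistic integrates squared curve
differences over lineage pairs; end/early statistics take the largest
pairwise mean difference in the last/first pseudotime decile. The null
shuffles lineage labels within 10 pseudotime bins. With `n_perm`
permutations the smallest attainable p is `1/(n_perm+1)`; BH adjustment
over thousands of genes can therefore be starved at small `n_perm`, and
the pipeline falls back to a top-N-by-statistic selection among
raw-significant genes (N = 50 by default) — the rank-based analogue of
fixed statistic thresholds used with parametric Wald tests.

Gene modules: per-gene concatenated lineage curves are mean-centered
(shape, not level), L2-normalized, embedded by PCA to 25 components
(replacing a UMAP embedding — deterministic and sufficient for
archetype separation), and clustered by Leiden on a similarity-weighted
cosine kNN graph (k adapts to `n/5`, capped at 15). The Leiden
resolution default is 0.1, recalibrated for the PCA embedding; the 0.3
value customary on UMAP graphs over-merges here. Module summary curves
are min-max scaled to [−2, 2]. Per-lineage in-cis annotation collects
the clones holding ≥ 5 % of a lineage's cells and flags a gene in-cis
iff the clone medians differ at its bin; single-clone lineages have no
CN contrast and are logged, not errors.

## Chromatin status

Promoters are 2-kb windows upstream of the TSS (strand-aware, clipped
at 0). Per-mark signal is replicate-averaged RPM over replicate-averaged
input RPM, with a 0.5-read pseudo-count when input is zero. Modules are
compared to the repressed control block by one-way ANOVA per mark on
log2 ratios — per-promoter ratios are the observations; replicates are
averaged first, since the replicate structure of the ANOVA is otherwise
underdetermined. A mark counts as enriched or depleted only when the
ANOVA is significant at α = 0.05 **and** the module-control difference
of mean log2 ratios exceeds 0.25: with hundreds of promoters the F-test
alone flags biologically meaningless shifts at the nominal 5 % rate,
which would corrupt roughly one module label in five. The decision
table (K4↑ & K27↓ → Active; K4↑ & K27 = → Bivalent; both = →
Repressed) is not exhaustive, so uncovered combinations are labeled
Unclassified rather than silently forced.

## Pipeline and formats

The orchestrated run chains QC → assignment → per-contrast DE →
cis/trans → dynamics → GSEA → trajectory → chromatin. Contrast clones
are the fittest (given a fitness map) or most abundant per passage and
condition, requiring ≥ 100 assigned cells (configurable); contrasts
without a qualifying clone are skipped and logged, and a run whose
trajectory yields a single usable lineage skips the between-lineage
stages rather than failing. Every output TSV carries a provenance
header (package version, seed, semantic config hash — never a
timestamp), so a rerun with the same config and seed is byte-identical;
this is asserted by a test. Formats: MatrixMarket integer triplets with
barcodes/features sidecars, long-format CN TSV, BED (0-based) and GTF
(1-based, converted on read), GMT gene sets, YAML configuration.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each complete in well under a minute of simulation-heavy compute on a
single core: 200 bins × 8 genes, 400 cells per sample for the study
generator; 1,500 cells for assignment recovery; 20 replicates × 2,000
genes × 400 cells for DE calibration; 600–900 cells for trajectory
fixtures; 20 seeds × 3 modules × 100 promoters for chromatin recovery.
All scale linearly through `SimulationParams`.

## Known limitations

* The multinomial EM ignores per-gene overdispersion in assignment;
  accuracy degrades when clones differ only in few, lowly expressed
  bins.
* The NB Wald test relies on asymptotic normality; with fewer than a
  few dozen cells per side its type-I control is untested here.
* Piecewise-linear centroid paths under-fit curved trajectories, and
  k-means with fixed k can split or merge true states; k is a knob, not
  an inference.
* Permutation p-value granularity bounds the smallest attainable
  adjusted p; raise `n_perm` for large gene universes.
* The chromatin ANOVA assumes promoters are exchangeable within a
  module; correlated promoters (shared domains) would inflate its
  effective sample size.
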