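# Methods

This note documents the statistical models, the numerical conventions, the
synthetic-data generator, and the design choices behind `gliastate`.

## Quality control and normalization

A cell is removed iff its total UMI count `n_c` is **below** 1000 or its
mitochondrial fraction is **above** 0.10. Both comparisons are strict by
design, so a cell at exactly 1000 UMIs or exactly 10% mitochondrial content
is retained; the thresholds are arguments and can be changed. Mitochondrial
genes are identified by the mouse symbol prefix `mt-` (case-insensitive)
unless an explicit gene list is given. Cells with zero total UMIs get a
mitochondrial fraction of 0 and are flagged separately (they fail the UMI
threshold anyway for any positive cutoff).

Size factors are computed **after** QC, on the surviving cells only:
`f_c = n_c / median(n)`, with the even-count median taken as the mean of
the central pair. Normalization divides each gene's count by the cell's
factor, `nUMI_{g,c} = n_{g,c} / f_c`; consequently every column of the
normalized matrix sums to the median pre-QC-surviving cell total, and
within-cell rank order is untouched. Genes are never filtered at this
stage — gene-level filters belong to HVG selection and the DE expression
filter, which have their own contracts.

## Highly variable genes, PCA, graph clustering

HVG selection operates on `log2(nUMI + 1)`: per gene, the mean and the
sample variance (ddof 1) are computed; genes are split into up to 20
quantile bins of the mean (the bin count shrinks so each bin keeps at least
~10 genes — z-scores within 1–2-gene bins are meaningless), the variance is
z-scored within each bin, and the top `n` genes by z are returned, ties
broken by gene identifier. Requesting more genes than have nonzero variance
is an error.

PCA runs on centered, unit-scaled log expression of the selected genes with
a full SVD (no randomized solver), components ordered by explained
variance, and a fixed sign convention: the largest-magnitude loading of
each component is positive. This makes embeddings reproducible across runs
and platforms.

The cell graph uses the `k = 15` nearest neighbors (Euclidean, in PC
space); edge weights are the Jaccard overlap of the two endpoints' neighbor
lists (shared-nearest-neighbor weighting). Louvain modularity is optimized
with python-igraph; Python's global RNG is seeded around the call, so a
fixed seed gives identical labels. Leiden (leidenalg, seeded) is available
behind `method="leiden"`. Cluster labels are relabeled by decreasing size.
Two degenerate-geometry conventions: if every cell has identical
coordinates a single cluster is returned, and singleton clusters are
permitted.

A known behavior worth stating: modularity optimization over-partitions
large *low-dimensional* point clouds (geometric kNN graphs have genuine
community structure at resolution 1). In the 30-dimensional PC embeddings
the pipeline produces, well-separated types are recovered exactly; for
small subclustering runs (a few hundred cells) `k` should grow with the
subset — the tests use `k = 30` for ~400-cell subsets. The top-level
clustering parameters (3000 HVGs, 30 PCs, k = 15, resolution 1.0) mirror
the subclustering recipe; all are exposed in the configuration.

Annotation assigns each cluster the marker set with the highest mean module
score over member cells (`score_c` = mean over set genes of
`log2(nUMI+1)`); exact ties go to the lexicographically first set name and
are flagged. The full clusters × sets score table is retained for audit.
Doublet-cluster flagging is off by default and heuristic: a cluster is
flagged when its second-best marker score comes within a margin of its
best, the default margin being 0.25 × the best score's excess over the
other clusters' median score for that same set. The margin rule is this
package's own construction (doublet clusters are usually identified by
inspection); it is exposed so users can pass a fixed margin instead.

Subclustering re-extracts the **raw** counts of one annotated type,
recomputes size factors on that subset (so the subset's own median total
becomes the normalization anchor), and reruns HVG → PCA → clustering.
`n_hvg`/`n_pcs` are clamped, with a warning, to what the subset supports.

Marker discovery is a one-vs-rest statistic per (cluster, gene): the
difference in mean log expression, and the AUROC computed by the rank-sum
identity with average ranks for ties. Reference mapping correlates a
cluster's mean log profile against reference type columns by Spearman
correlation over shared genes (≥10 required); constant columns give an
undefined correlation, reported as missing and never selected.

## Cellularity and composition tests

Cellularity is reported per animal: the percentage of that animal's
retained cells belonging to each type, and optionally the percentage within
a parent lineage (e.g. T-cell subtypes as a share of all T-cells).
Percentages per sample sum to 100 exactly. Flagged doublet clusters can be
excluded before counting.

Between-group comparisons are Welch (unequal-variance) two-sample t-tests
on the per-sample percentages, with Welch–Satterthwaite degrees of freedom
and two-sided p-values, annotated with conventional star bins (0.05 / 0.01
/ 0.001). Welch was chosen over the pooled test because the group sizes and
variances in this design are unequal; no multiple-testing correction is
applied across cell types, matching how such panels are conventionally
annotated (one star per comparison). Degenerate inputs have fixed
conventions: two constant equal groups give p = 1; constant unequal groups
are reported as undefined rather than infinitely significant.

Box summaries use type-7 (linear-interpolation) quartiles as hinges and
whiskers at the most extreme data values within 1.5 IQR of the hinges;
values beyond are listed individually as outliers.

## Pseudo-bulk and moderated differential expression

Pseudo-bulk columns are raw UMI sums per (sample, cell type). Columns
backed by fewer than 10 cells are dropped ("fewer than" strict: 10 cells
survive), and their cell and UMI totals are logged so global UMI
bookkeeping reconciles exactly. Aggregation never uses normalized values.

Size factors are median-of-ratios: genes positive in every column
contribute `count / geometric-mean` ratios, and the column's factor is the
median ratio. The median is taken on the log scale, so an even count of
genes combines the central pair geometrically — this is the reference
implementation's convention and is what the brute-force oracle in the test
suite reproduces. Factors are not rescaled to unit geometric mean.
`normalizedCount` is entry-wise division by the factor, used for gene-set
scores (mean of `log2(normalizedCount + 1)`) and visualization.

DE analysis per contrast: genes with at least 10 UMIs in at least three of
the analyzed pseudo-bulks are kept (inclusive comparisons). Log-CPM is
`log2((count + 0.5) / (L_j + 1) × 1e6)` with effective library sizes `L_j`
taken from the size factors, rescaled to preserve the geometric-mean column
total — voom must see the same relative scaling the normalized counts use.
Gene-wise OLS residual SDs give (mean log-count, √SD) pairs; a LOWESS curve
(span 0.5, 3 robustness iterations, delta 1% of the x-range) is evaluated
at each observation's fitted log-count and raised to the −4 power to give
precision weights. The predicted √SD is floored at 1e-4 to keep weights
finite when the trend dips to zero.

Weighted least squares then estimates the contrast per gene. Residual
variances are shrunk by empirical Bayes: the prior degrees of freedom `d0`
and prior variance `s0²` come from moment-matching the scaled-F model on
`log s²` (digamma/trigamma relations, Newton inversion of the trigamma).
When the observed spread of `log s²` does not exceed chi-square sampling
noise the prior is infinite and the common variance is the arithmetic mean
of the `s²` — matching limma's branch. Moderated t uses
`s̃²_g = (d0 s0² + d s²_g)/(d0 + d)` with `d0 + d` degrees of freedom,
capped at the pooled residual df over all genes. Setting `d0 = 0` disables
moderation and reproduces the ordinary WLS t exactly (tested at 1e-8).
The whole chain — log-CPM, weights, coefficients, t, p — agrees with
Bioconductor limma's `voom` + `eBayes` to ~1e-6 or better on shared inputs;
the test suite runs that comparison through `Rscript`.

BH-FDR is the step-up procedure, `q_(i) = min_{k≥i} p_(k)·m/k` capped at 1,
applied within each (cell type × contrast) gene list independently because
DEG counts are reported per cell type. DEG calling is strict on both sides:
`q < 0.01` **and** `|log2FC| > 1.5`; boundary genes are not DEGs.

## Bulk signatures

nRPKM is size-factor-adjusted RPKM:
`count / s_j / (length/1e3) / (D/1e6)` with `D` the median size-corrected
column total. The exact historical definition of this statistic lives in
prior literature; this formula is the package's documented stand-in and
reduces to classic RPKM when all factors are 1 and depths equal. Gene-set
scores are the mean of `log2(nRPKM + 1)` over set genes (absent genes
dropped with a warning; an entirely absent set is an error). Z-score
matrices standardize `log2(nRPKM)` per gene across samples (sample SD,
ddof 1) after clamping values below a floor, default −4 log2 units
(nRPKM ≈ 0.06); the floor also resolves `log2(0)`. The default floor is an
explicit, overridable package choice, not an inherited constant. Constant
genes get z ≡ 0 and a flag. Top-gene selection ranks set genes by mean z
within a reference sample group (e.g. the treated wild-type group),
descending, ties by identifier.

## The synthetic-data generator

`simulate_dataset` emulates the study design the analysis targets: four
genotypes with 3/3/6/6 animals, ~10 hippocampal cell types with fixed
baseline proportions, 10,000 target cells per sample (desk-scale fixtures
use 120–5,000), log-normal library sizes (σ = 0.3) around a mean of 2,500
UMIs, and negative-binomial counts with variance `μ + αμ²`, α = 0.1 by
default. Per cell type, a log-normal base expression profile is modified by
a marker block (8–10 genes, 8-fold elevated, near-silent in other types);
mitochondrial genes (named `mt-Sim*`) carry a fixed expected share of each
cell's UMIs (5% default, so a 10% QC cutoff removes a realistic tail).
Planted composition effects multiply a type's proportion within a genotype
(renormalized); per-sample type counts are multinomial, optionally
Dirichlet-multinomial. Planted DE effects multiply a gene's relative
expression by `2^lfc` within one (genotype, type); because profiles are
renormalized to keep library sizes calibrated, realized mean ratios carry a
small compositional bias toward the planted value (a few percent when
planted mass is small) — the same bias real sequencing has. Optional
doublets replace random same-sample cell pairs by their summed profiles.
All draws come from one seeded generator; identical config + seed gives
byte-identical fixtures.

`simulate_pseudobulk_counts` generates NB counts directly at the
pseudo-bulk level (log-normal gene means around a base of 50, log-normal
column depths, planted log2 fold-changes in one group) for DE calibration
and recovery studies.

What the generator does **not** emulate: ambient RNA, batch or sex effects,
UMI saturation, gene–gene correlation beyond cell-type structure, and
read-level artifacts. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to those real-data complications.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: shared fixtures
of 400–7,200 cells and 30–2,000 genes, 5 null-DE replicates of 2,000 genes,
20 composition replicates of 12 × 1,000–5,000 cells. These sizes keep the
full suite around half a minute while leaving wide margins on every
statistical criterion (e.g. planted-DE sensitivity ~92% against a 70%
floor). Every stochastic step is seeded; pipeline runs with the same
configuration and seed produce byte-identical output files, and the run
report carries a configuration hash (excluding the output directory) plus
per-stage cell bookkeeping that reconciles exactly.

## Known limitations

- The DE model is a two-group design per cell type; multi-factor designs,
  duplicate-correlation models and NB GLMs are out of scope.
- Cellularity tests treat per-animal percentages as independent normal
  observations; compositional transforms (CLR/ILR) are not applied.
- Doublet detection is cluster-level and heuristic; no per-cell scoring.
- Embedding coordinates (tSNE/UMAP) are deliberately not part of any
  quantitative contract; clusters are.
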