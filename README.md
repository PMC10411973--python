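# gliastate

Pseudo-bulk analysis of single-cell RNA-seq for glial state changes in
mouse neurodegeneration models — and the bulk RNA-seq signature layer that
goes with it.

The package is aimed at analysts working with droplet scRNA-seq of brain
tissue from multi-genotype mouse cohorts (e.g. a tauopathy allele crossed
with a kinase-dead immune modifier), who need per-animal statistics rather
than per-cell ones: which cell types expand or contract in a genotype, and
which genes change within a cell type, tested with proper biological
replication. It covers the full path from a raw UMI count matrix to those
answers, plus a negative-binomial simulator with planted ground truth so
every stage can be validated against known answers.

## The analysis in brief

1. **QC** — cells with fewer than 1000 total UMIs or more than 10%
   mitochondrial UMIs are discarded (strict comparisons; boundary cells are
   kept).
2. **Normalization** — median-ratio scaling. With `n_c` the total UMIs of
   cell `c`, the factor is `f_c = n_c / median_c'(n_c')` and
   `nUMI_{g,c} = n_{g,c} / f_c`, so every cell's total becomes the median
   cell total.
3. **Clustering** — log-transform, 3000 most-variable genes (dispersion
   z-scored within mean bins), top 30 PCs, shared-nearest-neighbor graph,
   Louvain modularity (Leiden available). Clusters are annotated by the
   marker gene set with the highest mean module score,
   `score_c = mean_{g in set} log2(nUMI_{g,c} + 1)`.
4. **Cellularity** — per-animal percentages of each cell type (of all
   cells, or of a parent lineage such as T-cells), compared between
   genotypes with Welch's t-test; box summaries use type-7 quartile hinges
   and 1.5·IQR whiskers.
5. **Pseudo-bulk** — raw UMIs summed per (sample, cell type); columns with
   fewer than 10 cells dropped; DESeq2-style median-of-ratios size factors;
   `normalizedCount = count / s_j`.
6. **Differential expression** — genes need ≥10 UMIs in ≥3 pseudo-bulks;
   voom precision weights (LOWESS mean–variance trend on log2-CPM,
   weights = predicted SD⁻⁴) feed gene-wise weighted least squares with
   empirical-Bayes variance moderation:
   `s̃²_g = (d0·s0² + d·s²_g)/(d0 + d)`, moderated t with `d0 + d` degrees
   of freedom, Benjamini–Hochberg FDR, and DEG calling at FDR < 0.01 and
   |log2FC| > 1.5. The whole chain matches Bioconductor limma to ~1e-10 on
   shared inputs (tested).
7. **Bulk signatures** — nRPKM (size-factor-adjusted RPKM), gene-set scores
   as the mean of log2(nRPKM + 1), per-gene z-score matrices with a low-end
   floor, and z-score-ranked top-gene selection within a reference group.

## Worked example

```python
import gliastate as gs

# a study-like simulated cohort: 4 genotypes (3+3+6+6 animals), 10 cell
# types, planted T-cell expansion and 30 planted microglial DE genes
de = {("P301S", "microglia", g): 2.0 for g in range(200, 215)}
de.update({("P301S", "microglia", g): -2.0 for g in range(215, 230)})
cfg = gs.default_config(target_cells_per_sample=400, n_genes=500, seed=3,
                        de_effects=de)
counts, annot, truth = gs.simulate_dataset(cfg)

filtered, report = gs.qc_filter(counts)
print(f"QC kept {report.n_kept}/{report.n_in} cells")

ann = annot.loc[filtered.cell_ids].assign(
    cell_type=truth.cell_type_of_cell.loc[filtered.cell_ids])
table = gs.cellularity(ann)
res = gs.compare_groups(table, "WT", "P301S", "T_cell")
print(f"T-cell % WT {res['mean_a']:.2f} vs P301S {res['mean_b']:.2f}: "
      f"t={res['t']:.2f}, p={res['p']:.4f} {res['stars']}")

pbm = gs.aggregate(filtered, ann)
results, summary = gs.per_celltype_de(pbm, "P301S_TPL2KD", "P301S")
print(results["microglia"].summary(top=3))
```

prints

```
QC kept 7188/7200 cells
T-cell % WT 1.17 vs P301S 3.13: t=-6.24, p=0.0004 ***
Moderated DE: P301S vs P301S_TPL2KD
  genes tested:      457
  residual df:       10
  prior df d0:       inf
  prior variance s0²: 1.048
  DEGs (q < 0.01, |log2FC| > 1.5): 30
           log2fc     t  p     s2  s2_post  q   deg
gene
Gene00200   2.007 68.68  0 0.9767    1.048  0  True
Gene00201   2.006 51.22  0 0.4649    1.048  0  True
Gene00202   2.044 50.74  0  1.828    1.048  0  True
```

The T-cell expansion is detected at the per-animal level (1.2% → 3.1% of
cells, Welch p = 0.0004), and all 30 planted microglial genes — and no
others — are called as DEGs, with log2 fold-change estimates at the planted
value of ±2.

A `gliastate` command exposes the same stages for shell use
(`simulate`, `qc`, `cluster`, `subcluster`, `cellularity`, `pseudobulk`,
`de`, `score`, `run`); see `gliastate --help`.

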