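"""Pseudo-bulk aggregation and size-factor normalization.

Cells are summed into one raw-count profile per (sample, cell type);
columns backed by fewer than 10 cells are dropped. The resulting
genes x pseudo-bulk matrix is normalized by DESeq2-style median-of-ratios
size factors and feeds both gene-set scoring and differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, validate_annotation

__all__ = [
    "PseudoBulkMatrix",
    "aggregate",
    "estimate_size_factors",
    "norm_counts",
    "pseudobulk_geneset_score",
]

log = logging.getLogger(__name__)


@dataclass
class PseudoBulkMatrix:
    """Genes x pseudo-bulk integer counts.

    Columns are a MultiIndex of (sample_id, cell_type, group); ``n_cells``
    records how many cells back each column. ``dropped`` logs the
    (sample, type) combinations discarded by the minimum-cell rule together
    with their cell and UMI totals, so UMI bookkeeping stays exact.
    """

    counts: pd.DataFrame
    n_cells: pd.Series
    min_cells: int
    dropped: pd.DataFrame

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def column_meta(self) -> pd.DataFrame:
        meta = self.counts.columns.to_frame(index=False)
        meta["n_cells"] = self.n_cells.to_numpy()
        return meta

    def for_cell_type(self, cell_type: str) -> "PseudoBulkMatrix":
        keep = self.counts.columns.get_level_values("cell_type") == cell_type
        if not keep.any():
            raise ValueError(f"no pseudo-bulk columns for cell type {cell_type!r}")
        return PseudoBulkMatrix(
            self.counts.loc[:, keep], self.n_cells[keep], self.min_cells, self.dropped
        )


def aggregate(
    counts: CountMatrix,
    annot: pd.DataFrame,
    cell_type_col: str = "cell_type",
    min_cells: int = 10,
) -> PseudoBulkMatrix:
    """Sum raw UMIs over cells per (sample, cell type).

    A (sample, type) column is kept iff it has at least ``min_cells`` cells
    ("fewer than 10" is strict: exactly 10 survives). Aggregation always
    uses raw counts, never normalized values.
    """
    annot = validate_annotation(annot, counts.cell_ids)
    if cell_type_col not in annot.columns:
        raise ValueError(f"annotation lacks a {cell_type_col!r} column")

    key = pd.MultiIndex.from_frame(
        annot[["sample_id", cell_type_col, "group"]].rename(
            columns={cell_type_col: "cell_type"}
        )
    )
    uniq, codes = np.unique(key.to_numpy(), return_inverse=True)
    # indicator matrix: cells x columns, then sparse matmul does the sums
    import scipy.sparse as sp

    ind = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(uniq)),
    )
    sums = np.asarray((counts.values @ ind).todense())
    ncells = np.bincount(codes, minlength=len(uniq))

    cols = pd.MultiIndex.from_tuples(list(uniq), names=["sample_id", "cell_type", "group"])
    frame = pd.DataFrame(sums, index=counts.gene_ids, columns=cols).astype(np.int64)
    ncells_s = pd.Series(ncells, index=cols, name="n_cells")

    keep = ncells_s >= min_cells
    dropped = pd.DataFrame(
        {
            "n_cells": ncells_s[~keep],
            "total_umi": frame.loc[:, ~keep].sum(axis=0),
        }
    )
    if len(dropped):
        log.info("pseudobulk: dropped %d column(s) below %d cells", len(dropped), min_cells)
    kept_frame = frame.loc[:, keep]
    if kept_frame.shape[1] == 0:
        raise ValueError(f"no (sample, cell type) combination reaches {min_cells} cells")
    order = kept_frame.columns.sortlevel(["sample_id", "cell_type"])[0]
    return PseudoBulkMatrix(kept_frame[order], ncells_s[keep][order], min_cells, dropped)


def estimate_size_factors(counts: pd.DataFrame | PseudoBulkMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with strictly positive counts in every column, compute its
    geometric mean across columns; the factor of column j is the median over
    those genes of count/geomean. The median is taken on the log scale, so
    with an even number of genes the two central ratios are combined by
    their geometric mean (the reference implementation's convention).
    Factors are not rescaled afterwards.
    """
    frame = counts.counts if isinstance(counts, PseudoBulkMatrix) else counts
    vals = frame.to_numpy(dtype=float)
    if vals.shape[1] == 1:
        return pd.Series([1.0], index=frame.columns, name="size_factor")
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every column; "
            "filter genes or add a pseudo-count before size-factor estimation"
        )
    logs = np.log(vals[allpos])
    log_geomean = logs.mean(axis=1)
    s = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(s, index=frame.columns, name="size_factor")


def norm_counts(counts: pd.DataFrame | PseudoBulkMatrix, s: pd.Series) -> pd.DataFrame:
    """normalizedCount: entry-wise division of each column by its size factor."""
    frame = counts.counts if isinstance(counts, PseudoBulkMatrix) else counts
    if len(s) != frame.shape[1] or not frame.columns.equals(s.index):
        raise ValueError("size factors do not match the matrix columns")
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return frame / s


def pseudobulk_geneset_score(norm: pd.DataFrame, geneset) -> pd.Series:
    """Per-column score: mean over set genes of log2(normalizedCount + 1)."""
    genes = pd.Index(geneset.genes if hasattr(geneset, "genes") else geneset)
    present = genes.intersection(norm.index)
    if len(present) == 0:
        raise ValueError("no gene of the set is present in the matrix")
    if len(present) < len(genes):
        import warnings

        warnings.warn(
            f"{len(genes) - len(present)} gene(s) of the set are absent and were dropped"
        )
    score = np.log2(norm.loc[present] + 1.0).mean(axis=0)
    score.name = getattr(geneset, "name", "geneset_score")
    return score
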