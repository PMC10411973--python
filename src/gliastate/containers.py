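"""Core in-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`, a sparse genes x cells UMI
matrix with gene and cell identifiers. Cells are columns throughout the
package, mirroring the convention of droplet-based count matrices on disk
(MatrixMarket triplets with genes as rows). Per-cell metadata travels as a
plain :class:`pandas.DataFrame` indexed by cell id (``CellAnnotation``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix", "validate_annotation"]


def _check_ids(ids: pd.Index, what: str) -> pd.Index:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} identifiers: {dups}")
    return ids


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.nnz:
            data = self.values.data
            if data.min() < 0:
                raise ValueError("negative UMI counts are not allowed")
            if not np.allclose(data, np.round(data)):
                raise ValueError("UMI counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell (the quantity n_c)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._cell_indexer(mask_or_ids)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def _cell_indexer(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.size != self.n_cells:
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(arr)
        if arr.dtype.kind in "iu":  # integer positions
            return arr
        idx = self.cell_ids.get_indexer_for(pd.Index(arr))
        if (idx < 0).any():
            missing = list(pd.Index(arr)[idx < 0][:5])
            raise KeyError(f"unknown cell id(s): {missing}")
        return idx

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of normalized UMIs (nUMI): raw counts divided
    by each cell's size factor. Sparsity pattern matches the raw counts."""

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    size_factors: np.ndarray = field(default=None)  # f_c used to build this

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def log2_row(self, gene: str) -> np.ndarray:
        """log2(nUMI + 1) for one gene across cells."""
        i = self.gene_ids.get_loc(gene)
        return np.log2(np.asarray(self.values[i].todense()).ravel() + 1.0)


REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "group")


def validate_annotation(annot: pd.DataFrame, cell_ids: pd.Index | None = None) -> pd.DataFrame:
    """Check a per-cell metadata table and align it to a cell id index."""
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation is missing required column(s): {missing}")
    if cell_ids is not None:
        absent = cell_ids.difference(annot.index)
        if len(absent):
            raise ValueError(
                f"{len(absent)} cells have no annotation row (e.g. {list(absent[:3])})"
            )
        annot = annot.loc[cell_ids]
    return annot
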