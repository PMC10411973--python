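"""Per-cell quality control and median-ratio UMI normalization.

QC discards cells with fewer than 1000 total UMIs or more than 10%
mitochondrial UMIs (both comparisons strict, so boundary cells survive).
Normalization divides each gene's count in cell ``c`` by the factor
``f_c = n_c / median(n)``, so every retained cell's column total becomes the
median pre-normalization total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "mito_fraction",
    "default_mito_genes",
    "qc_filter",
    "cell_size_factors",
    "normalize",
    "QCReport",
]

MITO_PREFIX = "mt-"


def default_mito_genes(counts: CountMatrix) -> pd.Index:
    """Genes whose symbol starts with 'mt-' (case-insensitive), the mouse
    mitochondrial gene-symbol convention."""
    sym = counts.gene_ids.astype(str).str.lower()
    return counts.gene_ids[sym.str.startswith(MITO_PREFIX)]


def mito_fraction(counts: CountMatrix, mito_genes) -> pd.Series:
    """Fraction of each cell's UMIs coming from mitochondrial genes.

    Cells with zero total UMIs get fraction 0; they are reported in the
    series' ``attrs['zero_total_cells']`` so callers can flag them.
    """
    mito_genes = pd.Index(mito_genes)
    unknown = mito_genes.difference(counts.gene_ids)
    if len(unknown):
        raise ValueError(f"unknown mitochondrial gene id(s): {sorted(unknown)}")
    totals = counts.cell_totals()
    ridx = counts.gene_ids.get_indexer_for(mito_genes)
    mito = np.asarray(counts.values[ridx].sum(axis=0)).ravel() if len(ridx) else np.zeros_like(totals, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    out = pd.Series(frac, index=counts.cell_ids, name="mito_fraction")
    out.attrs["zero_total_cells"] = list(counts.cell_ids[totals == 0])
    return out


@dataclass
class QCReport:
    """Bookkeeping of cell-level QC: one row per input cell."""

    table: pd.DataFrame  # cell_id index; total_umi, mito_fraction, kept, reason
    min_total_umi: float
    max_mito: float

    @property
    def n_in(self) -> int:
        return len(self.table)

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_removed_low_umi(self) -> int:
        return int(self.table["reason"].isin(["low_umi", "low_umi+high_mito"]).sum())

    @property
    def n_removed_high_mito(self) -> int:
        return int(self.table["reason"].isin(["high_mito", "low_umi+high_mito"]).sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_id")


def qc_filter(
    counts: CountMatrix,
    mito_genes=None,
    min_total_umi: float = 1000,
    max_mito: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Remove cells with total UMIs < ``min_total_umi`` or mitochondrial
    fraction > ``max_mito``. Boundary cells (exactly 1000 UMIs, exactly 10%
    mitochondrial) are retained."""
    if min_total_umi < 0:
        raise ValueError("min_total_umi must be >= 0")
    if not 0 <= max_mito <= 1:
        raise ValueError("max_mito must be in [0, 1]")
    if mito_genes is None:
        mito_genes = default_mito_genes(counts)
    totals = counts.cell_totals()
    frac = mito_fraction(counts, mito_genes).to_numpy()

    low = totals < min_total_umi
    high = frac > max_mito
    kept = ~(low | high)
    reason = np.where(
        low & high, "low_umi+high_mito", np.where(low, "low_umi", np.where(high, "high_mito", ""))
    )
    table = pd.DataFrame(
        {
            "total_umi": totals,
            "mito_fraction": frac,
            "kept": kept,
            "reason": reason,
        },
        index=counts.cell_ids,
    )
    report = QCReport(table=table, min_total_umi=min_total_umi, max_mito=max_mito)
    if not kept.any():
        warnings.warn("QC removed every cell; downstream stages will see an empty matrix")
    filtered = counts.subset_cells(kept)
    return filtered, report


def cell_size_factors(counts: CountMatrix) -> pd.Series:
    """Per-cell normalization factor f_c = n_c / median over cells of n.

    The median of an even number of cells is the mean of the two central
    values. Requires every cell to have at least one UMI.
    """
    if counts.n_cells < 1:
        raise ValueError("size factors need at least one cell")
    totals = counts.cell_totals().astype(float)
    if (totals == 0).any():
        bad = list(counts.cell_ids[totals == 0][:5])
        raise ValueError(f"cells with zero total UMIs have undefined size factors: {bad}")
    med = float(np.median(totals))
    f = pd.Series(totals / med, index=counts.cell_ids, name="size_factor")
    f.attrs["median_total"] = med
    return f


def normalize(counts: CountMatrix, f: pd.Series) -> NormalizedMatrix:
    """Divide each cell's counts by its factor: nUMI_{g,c} = n_{g,c} / f_c.

    Sparsity pattern is preserved and each column's total becomes the
    median pre-normalization cell total.
    """
    if len(f) != counts.n_cells or not counts.cell_ids.equals(pd.Index(f.index)):
        raise ValueError("size factors do not match the matrix's cell set")
    fv = f.to_numpy(dtype=float)
    if (fv <= 0).any():
        raise ValueError("size factors must be positive")
    inv = sp.diags(1.0 / fv)
    vals = (counts.values @ inv).tocsr()
    return NormalizedMatrix(vals, counts.gene_ids, counts.cell_ids, size_factors=fv)


def normalize_counts(counts: CountMatrix) -> NormalizedMatrix:
    """Convenience: size factors + normalization in one call."""
    return normalize(counts, cell_size_factors(counts))
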