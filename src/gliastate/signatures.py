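"""Gene sets and bulk RNA-seq signature analysis.

Covers the bulk layer of the study: nRPKM normalization (size-factor
adjusted reads per kilobase per million), gene-set scores as the mean of
log2(nRPKM + 1) over set genes, per-gene z-score matrices for heatmaps
(with a configurable low-end floor on the log scale), and z-score-ranked
top-gene selection within a reference group of samples (e.g. the top 60
disease-associated-microglia genes ranked in LPS-treated wild-type brains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pseudobulk import estimate_size_factors

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "nrpkm",
    "bulk_geneset_score",
    "zscore_matrix",
    "select_top_genes_by_zscore",
]


@dataclass
class GeneSet:
    """A named gene list with a provenance note."""

    name: str
    genes: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dups = pd.Index(self.genes)
            raise ValueError(
                f"gene set {self.name!r} has duplicate genes: "
                f"{sorted(dups[dups.duplicated()].unique())[:5]}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, gene_index: pd.Index) -> pd.Index:
        present = pd.Index(self.genes).intersection(gene_index)
        if len(present) == 0:
            raise ValueError(f"no gene of set {self.name!r} is present in the matrix")
        if len(present) < len(self.genes):
            warnings.warn(
                f"set {self.name!r}: {len(self.genes) - len(present)} gene(s) absent, dropped"
            )
        return present


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need name, description and >=1 gene")
        sets.append(GeneSet(name=parts[0], genes=[g for g in parts[2:] if g], source=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    lines = ["\t".join([s.name, s.source or "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def nrpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Size-factor-normalized RPKM.

    nRPKM_{g,j} = count_{g,j} / s_j / (length_g/1e3) / (D/1e6) where D is
    the median across samples of the size-factor-corrected column total.
    With all factors 1 and equal column totals this reduces to classic RPKM.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:5])
        raise ValueError(f"gene length missing for: {missing}")
    if (lengths <= 0).any():
        bad = list(counts.index[lengths <= 0][:5])
        raise ValueError(f"non-positive gene length for: {bad}")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if not counts.columns.equals(size_factors.index):
        raise ValueError("size factors do not match the count columns")
    corrected = counts / size_factors
    depth = float(np.median(corrected.sum(axis=0)))
    out = corrected.div(lengths / 1e3, axis=0) / (depth / 1e6)
    out.attrs["effective_depth"] = depth
    return out


def bulk_geneset_score(expr: pd.DataFrame, geneset: GeneSet) -> pd.Series:
    """Per-sample score: mean over set genes of log2(nRPKM + 1)."""
    present = geneset.present_in(expr.index)
    score = np.log2(expr.loc[present] + 1.0).mean(axis=0)
    score.name = geneset.name
    return score


def zscore_matrix(expr: pd.DataFrame, floor: float = -4.0) -> pd.DataFrame:
    """Per-gene z-scores of floored log2 expression across samples.

    log2 values below ``floor`` (default −4, i.e. nRPKM ≈ 0.06) are clamped
    to the floor before standardizing; this also resolves log2(0) = −inf.
    Genes constant across samples get z ≡ 0 and are listed in
    ``attrs['constant_genes']``. Sample SD uses ddof = 1.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores need at least two samples")
    with np.errstate(divide="ignore"):
        x = np.log2(expr.to_numpy(dtype=float))
    x = np.maximum(x, floor)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    out.attrs["constant_genes"] = list(expr.index[constant])
    out.attrs["floor"] = floor
    return out


def select_top_genes_by_zscore(
    z: pd.DataFrame,
    geneset: GeneSet,
    reference_samples,
    n: int = 60,
) -> list[str]:
    """Top ``n`` set genes by mean z-score within a reference sample group,
    descending; ties broken by gene identifier."""
    ref = pd.Index(reference_samples)
    missing = ref.difference(z.columns)
    if len(ref) == 0 or len(missing):
        raise ValueError(f"reference samples absent from the matrix: {list(missing)}")
    present = geneset.present_in(z.index)
    if n > len(present):
        raise ValueError(
            f"asked for {n} genes but only {len(present)} set genes are present"
        )
    mean_z = z.loc[present, ref].mean(axis=1)
    ranked = mean_z.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n])
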