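"""End-to-end orchestration: ingest or simulate, QC, normalize, cluster,
annotate, composition, pseudo-bulk, differential expression.

``run_pipeline`` executes the stages in order with structured per-stage
bookkeeping (cells in/out, warnings) and writes plain-text outputs plus a
manifest, so an identical config and seed reproduces every file byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import cluster as cl
from . import composition as comp
from . import diffexp as de
from . import pseudobulk as pb
from .containers import CountMatrix, validate_annotation
from .qcnorm import cell_size_factors, normalize, qc_filter
from .signatures import GeneSet, read_gmt
from .simdata import SimConfig, simulate_dataset

__all__ = ["PipelineConfig", "RunReport", "load_counts", "load_fixture", "run_pipeline",
           "marker_sets_from_gene_names"]

log = logging.getLogger(__name__)


def load_counts(path) -> CountMatrix:
    """Load a count matrix from an MTX fixture directory or a dense TSV.

    MTX directories hold ``matrix.mtx`` (1-based MatrixMarket triplets,
    genes x cells), ``genes.tsv`` and ``barcodes.tsv``. Dense TSVs have
    genes as rows and cells as columns. Duplicate gene symbols are
    disambiguated with ``.1``, ``.2``... suffixes in file order.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        try:
            values = scipy.io.mmread(mtx)
        except Exception as exc:  # malformed header or body
            raise ValueError(f"{mtx}: malformed MatrixMarket file: {exc}") from exc
        values = sp.csr_matrix(values)
        _validate_mtx_entries(values, mtx)
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        gene_ids = _dedupe(pd.Index(genes.astype(str)))
        return CountMatrix(values.astype(np.int64), gene_ids, pd.Index(cells.astype(str)))
    frame = pd.read_csv(path, sep="\t", index_col=0)
    vals = frame.to_numpy()
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        bad = np.argwhere((vals < 0) | ~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"{path}: non-count entry at data line {bad[0] + 2} (gene {frame.index[bad[0]]!r})"
        )
    gene_ids = _dedupe(pd.Index(frame.index.astype(str)))
    return CountMatrix(
        sp.csr_matrix(vals.astype(np.int64)), gene_ids, pd.Index(frame.columns.astype(str))
    )


def _validate_mtx_entries(values: sp.csr_matrix, mtx_path: Path) -> None:
    data = values.data
    if data.size and (data.min() < 0 or not np.allclose(data, np.round(data))):
        # locate the first offending body line for the error message
        with open(mtx_path) as fh:
            body_started = False
            for ln, line in enumerate(fh, start=1):
                if line.startswith("%"):
                    continue
                if not body_started:
                    body_started = True  # dimensions line
                    continue
                parts = line.split()
                if len(parts) == 3:
                    v = float(parts[2])
                    if v < 0 or v != round(v):
                        raise ValueError(f"{mtx_path}:{ln}: invalid count entry {parts[2]}")
        raise ValueError(f"{mtx_path}: invalid (negative or fractional) count entries")


def _dedupe(ids: pd.Index) -> pd.Index:
    if not ids.has_duplicates:
        return ids
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        k = seen.get(g, 0)
        out.append(g if k == 0 else f"{g}.{k}")
        seen[g] = k + 1
    warnings.warn("duplicate gene symbols disambiguated with .1/.2 suffixes")
    return pd.Index(out)


def load_fixture(path) -> tuple[CountMatrix, pd.DataFrame]:
    """Load counts and per-cell metadata from a fixture directory."""
    path = Path(path)
    counts = load_counts(path)
    meta = pd.read_csv(path / "metadata.tsv", sep="\t", index_col="cell_id")
    meta.index = meta.index.astype(str)
    meta = validate_annotation(meta, counts.cell_ids)
    return counts, meta


def marker_sets_from_gene_names(gene_ids: pd.Index, prefix: str = "Mk-") -> list[GeneSet]:
    """Recover marker gene sets from the simulator's naming convention
    (``Mk-<type>-<k>``); used when no GMT file is supplied for synthetic data."""
    groups: dict[str, list[str]] = {}
    for g in gene_ids:
        if g.startswith(prefix):
            t = g[len(prefix):].rsplit("-", 1)[0]
            groups.setdefault(t, []).append(g)
    return [GeneSet(t, sorted(genes), source="simulated markers") for t, genes in sorted(groups.items())]


@dataclass
class PipelineConfig:
    """Everything a run needs; every study threshold is a default here."""

    input_dir: str | None = None  # fixture directory; mutually exclusive with sim
    sim: SimConfig | None = None
    out_dir: str = "gliastate_run"
    min_total_umi: float = 1000.0
    max_mito: float = 0.10
    n_hvg: int = 3000
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 1.0
    cluster_method: str = "louvain"
    gene_sets_gmt: str | None = None
    exclude_doublet_clusters: bool = False
    subcluster_types: tuple = ()
    composition_comparisons: tuple = ()  # (group_a, group_b) pairs
    composition_cell_types: tuple = ()  # empty = all
    de_contrast: tuple | None = None  # (reference, treatment)
    min_cells_pseudobulk: int = 10
    fdr: float = 0.01
    lfc: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("exactly one of input_dir or sim must be given")
        if self.input_dir is not None:
            p = Path(self.input_dir)
            for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "metadata.tsv"):
                if not (p / f).exists():
                    raise ValueError(f"input file missing: {p / f}")
        if self.gene_sets_gmt is not None and not Path(self.gene_sets_gmt).exists():
            raise ValueError(f"gene set file missing: {self.gene_sets_gmt}")
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must be in [0, 1]")
        if self.min_total_umi < 0 or self.fdr <= 0 or self.lfc < 0:
            raise ValueError("thresholds out of range")

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items()}
            return sorted(o) if isinstance(o, set) else str(o)

        # out_dir is where results land, not what they are: keep it out of
        # the identity hash so relocated runs still compare equal
        base = {k: v for k, v in asdict(self).items() if k not in ("sim", "out_dir")}
        if self.sim is not None:
            base["sim"] = {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in vars(self.sim).items()
            }
        blob = json.dumps(base, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record of a pipeline run."""

    config_hash: str
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        if any(s["stage"] == stage for s in self.stages):
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages.append({"stage": stage, **info})
        log.info("stage %-12s %s", stage, info)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "version": self.version, "stages": self.stages},
                indent=1,
                default=str,
            )
        )


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns (RunReport, dict of result objects).

    Stage order: ingest/simulate → QC → normalize → HVG/PCA/cluster →
    annotate (+ optional doublet flagging) → cellularity (+ group tests) →
    pseudo-bulk → per-cell-type DE. Outputs land under ``config.out_dir``.
    """
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), version=__version__)
    artifacts: dict = {}

    # --- ingest -----------------------------------------------------------
    if config.sim is not None:
        counts, annot, truth = simulate_dataset(config.sim)
        artifacts["truth"] = truth
        report.record("ingest", source="simulated", n_genes=counts.n_genes, n_cells=counts.n_cells)
    else:
        counts, annot = load_fixture(config.input_dir)
        report.record("ingest", source=str(config.input_dir), n_genes=counts.n_genes,
                      n_cells=counts.n_cells)

    # --- QC ---------------------------------------------------------------
    filtered, qcrep = qc_filter(counts, min_total_umi=config.min_total_umi, max_mito=config.max_mito)
    qcrep.to_tsv(out / "qc_report.tsv")
    annot = annot.loc[filtered.cell_ids]
    report.record(
        "qc",
        cells_in=qcrep.n_in,
        cells_kept=qcrep.n_kept,
        cells_removed=qcrep.n_in - qcrep.n_kept,
        removed_low_umi=qcrep.n_removed_low_umi,
        removed_high_mito=qcrep.n_removed_high_mito,
    )
    artifacts["qc_report"] = qcrep

    # --- normalize --------------------------------------------------------
    f = cell_size_factors(filtered)
    norm = normalize(filtered, f)
    report.record("normalize", median_total=f.attrs["median_total"])

    # --- cluster ----------------------------------------------------------
    n_variable = _count_variable_genes(norm)
    n_hvg = min(config.n_hvg, n_variable)
    hvg = cl.select_hvg(norm, n=n_hvg)
    n_pcs = min(config.n_pcs, min(len(hvg), norm.n_cells) - 1)
    pcs = cl.pca_embed(norm, hvg, n_pcs=n_pcs)
    assign = cl.louvain_cluster(
        pcs,
        k_neighbors=config.k_neighbors,
        resolution=config.resolution,
        seed=config.seed,
        method=config.cluster_method,
    )
    report.record("cluster", n_hvg=n_hvg, n_pcs=n_pcs, n_clusters=len(assign.cluster_ids))
    artifacts["clusters"] = assign

    # --- annotate ---------------------------------------------------------
    if config.gene_sets_gmt is not None:
        marker_sets = read_gmt(config.gene_sets_gmt)
    else:
        marker_sets = marker_sets_from_gene_names(counts.gene_ids)
    if not marker_sets:
        raise ValueError("no marker gene sets available for annotation")
    labels = cl.annotate_clusters(assign, norm, marker_sets)
    cell_types = labels.labels_for_cells(assign)
    flagged: list = []
    if config.exclude_doublet_clusters and len(marker_sets) > 1:
        flagged = cl.flag_doublet_clusters(labels)
    annot = annot.assign(cluster=assign.labels, cell_type=cell_types)
    annot.to_csv(out / "cell_annotation.tsv", sep="\t", index_label="cell_id")
    report.record("annotate", n_sets=len(marker_sets), flagged_clusters=list(flagged),
                  ties=list(labels.ties))
    artifacts["annotation"] = labels

    # --- composition ------------------------------------------------------
    table = comp.cellularity(
        annot, exclude_clusters=set(flagged) if flagged else None
    )
    table.to_csv(out / "cellularity.tsv", sep="\t", index=False)
    comparisons = []
    for ga, gb in config.composition_comparisons:
        types = config.composition_cell_types or sorted(table["cell_type"].unique())
        for ct in types:
            comparisons.append(comp.compare_groups(table, ga, gb, ct))
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "composition_tests.tsv", sep="\t", index=False)
    report.record("composition", n_rows=len(table), n_tests=len(comparisons))
    artifacts["cellularity"] = table
    artifacts["composition_tests"] = pd.DataFrame(comparisons) if comparisons else None

    # --- pseudo-bulk ------------------------------------------------------
    keep_cells = (
        (~annot["cluster"].isin(flagged)).to_numpy() if flagged else np.ones(len(annot), bool)
    )
    pbm = pb.aggregate(
        filtered.subset_cells(keep_cells),
        annot[keep_cells],
        min_cells=config.min_cells_pseudobulk,
    )
    meta = pbm.column_meta()
    s = pb.estimate_size_factors(pbm)
    meta["size_factor"] = s.to_numpy()
    flat = pbm.counts.copy()
    flat.columns = ["|".join(map(str, c)) for c in pbm.counts.columns]
    flat.to_csv(out / "pseudobulk_counts.tsv", sep="\t", index_label="gene")
    meta.to_csv(out / "pseudobulk_meta.tsv", sep="\t", index=False)
    report.record("pseudobulk", n_columns=pbm.n_columns, n_dropped=len(pbm.dropped))
    artifacts["pseudobulk"] = pbm
    artifacts["size_factors"] = s

    # --- differential expression -----------------------------------------
    if config.de_contrast is not None:
        ref, trt = config.de_contrast
        results, summary = de.per_celltype_de(
            pbm, ref, trt, fdr=config.fdr, lfc=config.lfc
        )
        for ct, res in results.items():
            res.table.to_csv(out / f"de_{ct}_{trt}_vs_{ref}.tsv", sep="\t", index_label="gene")
        summary.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        report.record("diffexp", contrast=f"{trt} vs {ref}",
                      n_celltypes=len(results),
                      total_degs=int(np.nansum(summary["n_degs"].to_numpy())))
        artifacts["de_results"] = results
        artifacts["deg_summary"] = summary

    report.to_json(out / "run_report.json")
    manifest = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report, artifacts


def _count_variable_genes(norm) -> int:
    logx = norm.values.copy().tocsr()
    logx.data = np.log2(logx.data + 1.0)
    s1 = np.asarray(logx.sum(axis=1)).ravel()
    s2 = np.asarray(logx.multiply(logx).sum(axis=1)).ravel()
    n = norm.n_cells
    var = (s2 - s1**2 / n) / max(n - 1, 1)
    return int((var > 1e-12).sum())
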