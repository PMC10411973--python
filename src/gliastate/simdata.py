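"""Synthetic scRNA-seq and pseudo-bulk count generation with known truth.

The single-cell generator emulates a multi-genotype mouse hippocampus
design: several animals per genotype, ~10 cell types with genotype-dependent
composition (e.g. T-cell expansion in tauopathy samples), cell-type marker
blocks, planted cell-type x genotype differential expression, mitochondrial
genes carrying a configurable share of each cell's UMIs, log-normal library
sizes and negative-binomial counts (variance mu + alpha*mu^2).

Every draw flows from a single :class:`numpy.random.Generator`, so an
identical config and seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_config",
    "simulate_dataset",
    "simulate_pseudobulk_counts",
    "write_fixture",
    "read_truth",
]

#: genotype labels of the emulated design, in display order
DEFAULT_GROUPS = ("WT", "TPL2KD", "P301S", "P301S_TPL2KD")

#: hippocampal cell types with baseline proportions (sorted-cell mix)
DEFAULT_CELL_TYPES = (
    ("astrocyte", 0.18),
    ("microglia", 0.30),
    ("oligodendrocyte", 0.16),
    ("OPC", 0.06),
    ("endothelial", 0.10),
    ("VSMC", 0.04),
    ("neuron", 0.08),
    ("ependymal", 0.03),
    ("macrophage", 0.04),
    ("T_cell", 0.01),
)


@dataclass
class SimConfig:
    """Ground-truth description of a simulated dataset.

    ``animals_per_group`` may be a single count or one count per group.
    ``composition_effects`` maps (group, cell_type) to a fold-change applied
    to that type's baseline proportion (proportions are renormalized per
    group). ``de_effects`` maps (group, cell_type, gene_index) to a planted
    log2 fold-change relative to the reference expression of that type.
    """

    n_groups: int = 4
    animals_per_group: int | tuple = (3, 3, 6, 6)
    group_names: tuple = DEFAULT_GROUPS
    cell_types: tuple = DEFAULT_CELL_TYPES
    composition_effects: dict = field(default_factory=dict)
    n_genes: int = 2000
    marker_genes_per_type: int = 10
    marker_fold: float = 8.0
    marker_blocks: dict | None = None  # cell_type -> list of gene indices
    de_effects: dict = field(default_factory=dict)
    mean_library_size: float = 2500.0
    library_sigma: float = 0.3
    nb_dispersion: float = 0.1
    mito_gene_count: int = 13
    mito_fraction_mean: float = 0.05
    target_cells_per_sample: int = 10_000
    composition_concentration: float | None = None  # Dirichlet overdispersion; None = pure multinomial
    doublet_rate: float = 0.0
    doublet_types: tuple | None = None  # restrict doublet parents to this pair
    seed: int = 0

    def validate(self) -> None:
        props = np.array([p for _, p in self.cell_types], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"baseline proportions sum to {props.sum()}, not 1")
        if ((props < 0) | (props > 1)).any():
            raise ValueError("baseline proportions must lie in [0, 1]")
        if self.nb_dispersion is not None and self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")
        if not 0 <= self.mito_fraction_mean <= 1:
            raise ValueError("mito_fraction_mean must be a fraction in [0, 1]")
        if not 0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5)")
        for c in ("n_groups", "n_genes", "target_cells_per_sample"):
            if getattr(self, c) < 1:
                raise ValueError(f"{c} must be >= 1")
        if self.mito_gene_count < 0 or self.mito_gene_count >= self.n_genes:
            raise ValueError("mito_gene_count must be in [0, n_genes)")
        names = self.type_names()
        for (g, t), fc in self.composition_effects.items():
            if t not in names or g not in self.group_names[: self.n_groups]:
                raise ValueError(f"composition effect on unknown (group, type) ({g}, {t})")
            if fc <= 0:
                raise ValueError("composition fold-changes must be positive")
        for (g, t, gi) in self.de_effects:
            if gi < 0 or gi >= self.n_genes:
                raise ValueError(f"planted DE gene index {gi} out of range")
            if t not in names:
                raise ValueError(f"planted DE on unknown cell type {t}")

    def type_names(self) -> list[str]:
        return [name for name, _ in self.cell_types]

    def groups(self) -> list[str]:
        return list(self.group_names[: self.n_groups])

    def animals(self) -> list[int]:
        a = self.animals_per_group
        if np.isscalar(a):
            return [int(a)] * self.n_groups
        if len(a) < self.n_groups:
            raise ValueError("animals_per_group shorter than n_groups")
        return [int(x) for x in a[: self.n_groups]]


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_type_of_cell: pd.Series  # cell_id -> true type ('doublet:a+b' for doublets)
    planted_de: pd.DataFrame  # columns group, cell_type, gene, log2fc
    planted_composition: pd.DataFrame  # (sample_id, cell_type) -> expected proportion

    def true_labels(self, cell_ids) -> np.ndarray:
        return self.cell_type_of_cell.loc[cell_ids].to_numpy()


def default_config(**overrides) -> SimConfig:
    """The study-like default: 4 genotypes (3/3/6/6 animals), T-cell
    expansion in tauopathy groups partially normalized by kinase-dead TPL2,
    and microglial DE between the two tauopathy genotypes."""
    cfg = SimConfig(**overrides)
    if not cfg.composition_effects and cfg.group_names == DEFAULT_GROUPS:
        cfg.composition_effects = {
            ("P301S", "T_cell"): 3.0,
            ("P301S_TPL2KD", "T_cell"): 1.8,
        }
    return cfg


def _marker_blocks(cfg: SimConfig) -> dict:
    if cfg.marker_blocks is not None:
        return {t: np.asarray(ix, dtype=int) for t, ix in cfg.marker_blocks.items()}
    blocks = {}
    start = 0
    for name in cfg.type_names():
        stop = start + cfg.marker_genes_per_type
        if stop > cfg.n_genes - cfg.mito_gene_count:
            raise ValueError("not enough genes for the requested marker blocks")
        blocks[name] = np.arange(start, stop)
        start = stop
    return blocks


def _gene_names(cfg: SimConfig, blocks: dict) -> pd.Index:
    names = np.array([f"Gene{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    for t, ix in blocks.items():
        for k, i in enumerate(ix):
            names[i] = f"Mk-{t}-{k:02d}"
    for k in range(cfg.mito_gene_count):
        names[cfg.n_genes - cfg.mito_gene_count + k] = f"mt-Sim{k:02d}"
    return pd.Index(names, name="gene")


def _expression_profiles(cfg: SimConfig, blocks: dict, rng: np.random.Generator) -> np.ndarray:
    """Relative expression per (cell type, gene); rows sum to 1."""
    n_types = len(cfg.cell_types)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    profiles = np.tile(base, (n_types, 1))
    for ti, name in enumerate(cfg.type_names()):
        profiles[ti, blocks[name]] *= cfg.marker_fold
        # markers of *other* types are near-silent in this type
        for other, ix in blocks.items():
            if other != name:
                profiles[ti, ix] *= 0.02
    mito = np.arange(cfg.n_genes - cfg.mito_gene_count, cfg.n_genes)
    if cfg.mito_gene_count:
        nonmito = np.setdiff1d(np.arange(cfg.n_genes), mito)
        for ti in range(n_types):
            s = profiles[ti, nonmito].sum()
            profiles[ti, nonmito] *= (1.0 - cfg.mito_fraction_mean) / s
            profiles[ti, mito] = cfg.mito_fraction_mean / cfg.mito_gene_count
    else:
        profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles


def _group_proportions(cfg: SimConfig) -> pd.DataFrame:
    base = np.array([p for _, p in cfg.cell_types], dtype=float)
    rows = {}
    for g in cfg.groups():
        p = base.copy()
        for ti, t in enumerate(cfg.type_names()):
            fc = cfg.composition_effects.get((g, t))
            if fc is not None:
                p[ti] *= fc
        rows[g] = p / p.sum()
    return pd.DataFrame(rows, index=cfg.type_names()).T


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw a full dataset: counts, per-cell metadata, and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks = _marker_blocks(config)
    gene_ids = _gene_names(config, blocks)
    profiles = _expression_profiles(config, blocks, rng)
    group_props = _group_proportions(config)
    type_names = config.type_names()
    type_index = {t: i for i, t in enumerate(type_names)}

    # per-(group, type) profiles with planted DE applied, renormalized so each
    # cell's expected library size stays at the drawn value (compositional)
    gt_profiles: dict[tuple[str, str], np.ndarray] = {}
    for g in config.groups():
        for t in type_names:
            prof = profiles[type_index[t]].copy()
            for (eg, et, gi), lfc in config.de_effects.items():
                if eg == g and et == t:
                    prof[gi] *= 2.0**lfc
            gt_profiles[(g, t)] = prof / prof.sum()

    col_blocks: list[sp.csc_matrix] = []
    cell_ids: list[str] = []
    samples: list[str] = []
    groups_of_cells: list[str] = []
    true_types: list[str] = []
    planted_comp_rows = []

    for gi_, (g, n_animals) in enumerate(zip(config.groups(), config.animals())):
        for a in range(n_animals):
            sample = f"{g}_s{a + 1}"
            props = group_props.loc[g].to_numpy()
            if config.composition_concentration is not None:
                props = rng.dirichlet(props * config.composition_concentration)
            n_cells = config.target_cells_per_sample
            type_counts = rng.multinomial(n_cells, props)
            for t, p in zip(type_names, group_props.loc[g]):
                planted_comp_rows.append((sample, g, t, float(p)))
            cell_no = 0
            for ti, t in enumerate(type_names):
                k = int(type_counts[ti])
                if k == 0:
                    continue
                mu_log = np.log(config.mean_library_size) - config.library_sigma**2 / 2
                libs = rng.lognormal(mean=mu_log, sigma=config.library_sigma, size=k)
                mu = np.outer(gt_profiles[(g, t)], libs)  # genes x cells
                block = _nb_draw(mu, config.nb_dispersion, rng)
                col_blocks.append(sp.csc_matrix(block))
                for _ in range(k):
                    cell_ids.append(f"{sample}_c{cell_no:05d}")
                    cell_no += 1
                samples.extend([sample] * k)
                groups_of_cells.extend([g] * k)
                true_types.extend([t] * k)

    values = sp.hstack(col_blocks, format="csr")
    cell_index = pd.Index(cell_ids, name="cell_id")
    true_series = pd.Series(true_types, index=cell_index, name="true_type")
    annot = pd.DataFrame(
        {"sample_id": samples, "group": groups_of_cells}, index=cell_index
    )

    if config.doublet_rate > 0:
        values, cell_index, annot, true_series = _inject_doublets(
            values, cell_index, annot, true_series, config, rng
        )

    counts = CountMatrix(values, gene_ids, cell_index)
    planted_de = pd.DataFrame(
        [
            {"group": g, "cell_type": t, "gene": gene_ids[gi], "log2fc": float(lfc)}
            for (g, t, gi), lfc in sorted(config.de_effects.items(), key=lambda kv: kv[0])
        ],
        columns=["group", "cell_type", "gene", "log2fc"],
    )
    planted_comp = pd.DataFrame(
        planted_comp_rows, columns=["sample_id", "group", "cell_type", "expected_proportion"]
    )
    truth = SimTruth(true_series, planted_de, planted_comp)
    return counts, annot, truth


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean mu, var mu + dispersion*mu^2) via gamma-Poisson mixing."""
    if dispersion is None or dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=mu * dispersion)
    return rng.poisson(lam)


def _inject_doublets(values, cell_index, annot, true_series, cfg, rng):
    """Replace random cell pairs (within a sample) by their summed profiles."""
    values = sp.csc_matrix(values)
    keep = np.ones(values.shape[1], dtype=bool)
    new_cols, new_rows = [], []
    for sample, sub in annot.groupby("sample_id", sort=False):
        pos = cell_index.get_indexer_for(sub.index)
        if cfg.doublet_types is not None:
            a_pos = pos[true_series.iloc[pos].isin([cfg.doublet_types[0]]).to_numpy()]
            b_pos = pos[true_series.iloc[pos].isin([cfg.doublet_types[1]]).to_numpy()]
            n_dbl = int(round(cfg.doublet_rate * len(pos)))
            n_dbl = min(n_dbl, len(a_pos), len(b_pos))
            pa = rng.choice(a_pos, size=n_dbl, replace=False)
            pb = rng.choice(b_pos, size=n_dbl, replace=False)
        else:
            n_dbl = int(round(cfg.doublet_rate * len(pos)))
            pick = rng.choice(pos, size=2 * n_dbl, replace=False)
            pa, pb = pick[:n_dbl], pick[n_dbl:]
        for j, (ia, ib) in enumerate(zip(pa, pb)):
            keep[ia] = keep[ib] = False
            col = np.asarray((values[:, ia] + values[:, ib]).todense()).ravel()
            new_cols.append(sp.csc_matrix(col[:, None]))
            ta, tb = sorted([true_series.iloc[ia], true_series.iloc[ib]])
            new_rows.append(
                {
                    "cell_id": f"{sample}_dbl{j:04d}",
                    "sample_id": sample,
                    "group": annot.iloc[ia]["group"],
                    "true_type": f"doublet:{ta}+{tb}",
                }
            )
    kept_vals = values[:, keep]
    kept_ids = cell_index[keep]
    parts = [kept_vals] + new_cols
    out_vals = sp.hstack(parts, format="csr")
    extra = pd.DataFrame(new_rows).set_index("cell_id")
    out_index = kept_ids.append(pd.Index(extra.index, name="cell_id"))
    out_annot = pd.concat([annot.loc[kept_ids], extra[["sample_id", "group"]]])
    out_truth = pd.concat([true_series.loc[kept_ids], extra["true_type"]])
    out_truth.name = "true_type"
    return out_vals, out_index, out_annot, out_truth


def simulate_pseudobulk_counts(
    n_genes: int = 2000,
    n_per_group: tuple[int, int] = (6, 6),
    base_mean: float = 50.0,
    mean_log2_sd: float = 1.0,
    dispersion: float = 0.1,
    n_de: int = 0,
    log2fc: float = 2.0,
    depth_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Negative-binomial counts at the pseudo-bulk level for two groups.

    Gene means are log-normal around ``base_mean``; the first ``n_de`` genes
    carry the planted log2 fold-change in group B (alternating sign). Column
    depths vary log-normally by ``depth_sd``. Returns (counts genes x
    columns, group label per column, index of planted DE genes).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    genes = pd.Index([f"Gene{i:05d}" for i in range(n_genes)], name="gene")
    cols = [f"A_pb{i}" for i in range(n_a)] + [f"B_pb{i}" for i in range(n_b)]
    groupv = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols, name="group")
    mu = base_mean * rng.lognormal(mean=-(mean_log2_sd * np.log(2)) ** 2 / 2,
                                   sigma=mean_log2_sd * np.log(2), size=n_genes)
    lfc = np.zeros(n_genes)
    if n_de:
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[:n_de] = signs * log2fc
    depth = rng.lognormal(mean=0.0, sigma=depth_sd, size=n_a + n_b)
    mu_mat = np.outer(mu, depth)
    mu_mat[:, n_a:] *= 2.0 ** lfc[:, None]
    counts = _nb_draw(mu_mat, dispersion, rng)
    frame = pd.DataFrame(counts, index=genes, columns=cols)
    return frame, groupv, genes[:n_de]


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(counts: CountMatrix, annot: pd.DataFrame, truth: SimTruth | None, path) -> None:
    """Write a fixture directory: matrix.mtx + genes/barcodes/metadata TSVs
    and (when truth is given) truth.json. Round-trips losslessly through
    :func:`gliastate.pipeline.load_counts`."""
    if counts.n_cells == 0:
        raise ValueError("refusing to write a fixture with zero cells")
    if counts.n_cells != len(annot):
        raise ValueError("annotation rows do not match the cell count")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(counts.values), field="integer")
    pd.Series(counts.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    annot.to_csv(path / "metadata.tsv", sep="\t", index_label="cell_id")
    if truth is not None:
        payload = {
            "cell_type_of_cell": truth.cell_type_of_cell.to_dict(),
            "planted_de": truth.planted_de.to_dict(orient="records"),
            "planted_composition": truth.planted_composition.to_dict(orient="records"),
        }
        (path / "truth.json").write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimTruth:
    payload = json.loads((Path(path) / "truth.json").read_text())
    cells = pd.Series(payload["cell_type_of_cell"], name="true_type")
    cells.index.name = "cell_id"
    return SimTruth(
        cell_type_of_cell=cells,
        planted_de=pd.DataFrame(payload["planted_de"], columns=["group", "cell_type", "gene", "log2fc"]),
        planted_composition=pd.DataFrame(
            payload["planted_composition"],
            columns=["sample_id", "group", "cell_type", "expected_proportion"],
        ),
    )
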