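"""HVG selection, PCA, graph clustering, annotation and marker discovery.

The clustering recipe mirrors droplet scRNA-seq practice: log-transform
normalized UMIs, keep the 3000 most variable genes (dispersion z-scored
within mean bins), embed with the top 30 principal components, build a
shared-nearest-neighbor graph and optimize Louvain modularity. Clusters are
annotated by the marker gene set with the highest mean module score, and
clusters co-expressing two disjoint type signatures can be flagged as
putative doublets. Subclustering re-normalizes the raw counts of one cell
type and repeats the recipe on that subset.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata, spearmanr
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, NormalizedMatrix
from .qcnorm import cell_size_factors, normalize

__all__ = [
    "ClusterAssignment",
    "CellTypeLabel",
    "select_hvg",
    "pca_embed",
    "louvain_cluster",
    "score_cells",
    "annotate_clusters",
    "subcluster",
    "find_markers",
    "flag_doublet_clusters",
    "map_to_reference",
    "cluster_mean_profiles",
]


def _log_expression(norm: NormalizedMatrix) -> sp.csr_matrix:
    """log2(nUMI + 1), preserving sparsity."""
    out = norm.values.copy().tocsr()
    out.data = np.log2(out.data + 1.0)
    return out


@dataclass
class ClusterAssignment:
    """A partition of cells into clusters, with the parameters that made it."""

    labels: pd.Series  # cell_id -> integer cluster id
    level: str = "top"  # or "subcluster-of:<type>"
    parameters: dict = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.labels.unique())

    def cells_of(self, cluster) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class CellTypeLabel:
    """Marker-score based cluster annotation with the full audit table."""

    cell_type: pd.Series  # cluster id -> type label
    scores: pd.DataFrame  # clusters x marker sets, mean module score
    ties: list = field(default_factory=list)  # clusters whose top two scores tied

    def labels_for_cells(self, assign: ClusterAssignment) -> pd.Series:
        out = assign.labels.map(self.cell_type)
        out.name = "cell_type"
        return out


def select_hvg(norm: NormalizedMatrix, n: int = 3000, n_bins: int = 20) -> list[str]:
    """The ``n`` most variable genes by binned standardized dispersion.

    Per gene, mean and variance (ddof=1) of log2(nUMI+1) are computed;
    genes are split into ``n_bins`` quantile bins of the mean and the
    variance is z-scored within each bin. Deterministic: ties break on the
    gene identifier.
    """
    logx = _log_expression(norm)
    n_cells = norm.n_cells
    if n_cells < 2:
        raise ValueError("HVG selection needs at least two cells")
    s1 = np.asarray(logx.sum(axis=1)).ravel()
    s2 = np.asarray(logx.multiply(logx).sum(axis=1)).ravel()
    mean = s1 / n_cells
    var = np.maximum((s2 - n_cells * mean**2) / (n_cells - 1), 0.0)
    variable = var > 0
    if int(variable.sum()) < n:
        raise ValueError(
            f"asked for {n} variable genes but only {int(variable.sum())} have "
            "nonzero variance"
        )
    stats = pd.DataFrame(
        {"mean": mean[variable], "dispersion": var[variable]},
        index=norm.gene_ids[variable],
    )
    # each mean-bin needs enough genes for the within-bin z-score to rank
    eff_bins = max(1, min(n_bins, len(stats) // 10))
    stats["bin"] = pd.qcut(stats["mean"], q=eff_bins, duplicates="drop", labels=False)
    z = stats.groupby("bin")["dispersion"].transform(
        lambda d: (d - d.mean()) / d.std(ddof=1) if len(d) > 1 and d.std(ddof=1) > 0 else d * 0.0
    )
    stats["z"] = z
    ranked = stats.sort_index().sort_values("z", ascending=False, kind="stable")
    return list(ranked.index[:n])


def pca_embed(norm: NormalizedMatrix, genes, n_pcs: int = 30) -> pd.DataFrame:
    """Principal-component scores of centered, unit-scaled log expression.

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude gene loading is
    positive. The explained-variance ratio is attached as
    ``attrs['explained_variance_ratio']``.
    """
    from sklearn.decomposition import PCA

    genes = pd.Index(genes)
    if norm.n_cells < 2:
        raise ValueError("PCA needs at least two cells")
    limit = min(len(genes), norm.n_cells) - 1
    if n_pcs > limit:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, cells) - 1 = {limit}")
    ridx = norm.gene_ids.get_indexer_for(genes)
    if (ridx < 0).any():
        raise ValueError("requested genes absent from the matrix")
    x = _log_expression(norm)[ridx].toarray().T  # cells x genes
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x /= sd
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-magnitude loading of each PC is positive
    for k in range(n_pcs):
        load = pca.components_[k]
        j = int(np.argmax(np.abs(load)))
        if load[j] < 0:
            scores[:, k] *= -1.0
            pca.components_[k] *= -1.0
    out = pd.DataFrame(
        scores, index=norm.cell_ids, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.copy()
    out.attrs["components"] = pd.DataFrame(
        pca.components_, index=out.columns, columns=genes
    )
    return out


def _snn_graph(coords: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """kNN graph (Euclidean) with shared-nearest-neighbor Jaccard weights."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self
    sets = sp.csr_matrix(
        (np.ones(idx.size), (np.repeat(np.arange(n), k_neighbors + 1), idx.ravel())),
        shape=(n, n),
    )
    shared = (sets @ sets.T).tocoo()
    knn_pairs = set()
    for i in range(n):
        for j in idx[i]:
            if i != j:
                knn_pairs.add((min(i, int(j)), max(i, int(j))))
    edges, weights = [], []
    size = k_neighbors + 1
    shared_lookup = {(min(i, j), max(i, j)): v for i, j, v in zip(shared.row, shared.col, shared.data) if i < j}
    for pair in sorted(knn_pairs):
        ov = shared_lookup.get(pair, 0.0)
        jac = ov / (2 * size - ov)
        edges.append(pair)
        weights.append(jac if jac > 0 else 1e-9)
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    return g


def louvain_cluster(
    scores: pd.DataFrame,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "louvain",
) -> ClusterAssignment:
    """Louvain (or Leiden) community detection on the SNN graph of cells.

    Deterministic for a fixed seed. Cells at identical coordinates form a
    degenerate geometry; if every cell coincides a single cluster is
    returned directly.
    """
    coords = scores.to_numpy(dtype=float)
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells ({n})")
    params = {
        "k_neighbors": k_neighbors,
        "resolution": resolution,
        "seed": seed,
        "method": method,
    }
    if np.allclose(coords, coords[0]):
        labels = pd.Series(0, index=scores.index, name="cluster")
        return ClusterAssignment(labels, parameters=params)
    g = _snn_graph(coords, k_neighbors)
    if method == "louvain":
        state = _pyrandom.getstate()
        try:
            _pyrandom.seed(seed)  # python-igraph draws from Python's RNG
            part = g.community_multilevel(weights="weight", resolution=resolution)
        finally:
            _pyrandom.setstate(state)
        membership = np.array(part.membership)
    elif method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = np.array(part.membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # relabel clusters by decreasing size, ties by first occurrence
    order = pd.Series(membership).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[m] for m in membership], index=scores.index, name="cluster")
    return ClusterAssignment(labels, parameters=params)


def score_cells(norm: NormalizedMatrix, geneset) -> pd.Series:
    """Per-cell module score: mean over set genes of log2(nUMI + 1)."""
    from .signatures import GeneSet

    if not isinstance(geneset, GeneSet):
        geneset = GeneSet("geneset", list(geneset))
    present = geneset.present_in(norm.gene_ids)
    ridx = norm.gene_ids.get_indexer_for(present)
    logx = norm.values[ridx].copy()
    logx.data = np.log2(logx.data + 1.0)
    score = np.asarray(logx.mean(axis=0)).ravel()
    return pd.Series(score, index=norm.cell_ids, name=geneset.name)


def annotate_clusters(
    assign: ClusterAssignment, norm: NormalizedMatrix, marker_sets
) -> CellTypeLabel:
    """Label each cluster with the marker set of highest mean module score.

    Ties go to the lexicographically first set name and are recorded in
    ``ties``. The full clusters x sets score table is kept for audit.
    """
    if not marker_sets:
        raise ValueError("at least one marker set is required")
    per_set = {}
    for gs in marker_sets:
        cell_scores = score_cells(norm, gs)
        per_set[gs.name] = cell_scores.groupby(assign.labels).mean()
    table = pd.DataFrame(per_set).sort_index()
    table = table[sorted(table.columns)]
    if table.isna().any().any():
        raise ValueError("a cluster has no cells in the matrix; inputs misaligned")
    best = table.idxmax(axis=1)  # idxmax takes the first (lexicographic) on ties
    ties = []
    for cl in table.index:
        row = table.loc[cl]
        if (row == row.max()).sum() > 1:
            ties.append(cl)
    best.name = "cell_type"
    return CellTypeLabel(cell_type=best, scores=table, ties=ties)


def subcluster(
    counts: CountMatrix,
    cell_types: pd.Series,
    target_type: str,
    n_hvg: int = 3000,
    n_pcs: int = 30,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "louvain",
) -> ClusterAssignment:
    """Extract one cell type from the *raw* counts, re-normalize the subset
    (its own median total), and rerun HVG selection, PCA and clustering.

    ``n_hvg`` and ``n_pcs`` are clamped to what the subset supports, with a
    warning, so the study-scale defaults stay usable on small datasets.
    """
    cell_types = cell_types.reindex(counts.cell_ids)
    mask = (cell_types == target_type).to_numpy()
    n_target = int(mask.sum())
    if n_target == 0:
        raise ValueError(f"no cells of type {target_type!r} in the dataset")
    if n_target < 2 * k_neighbors:
        raise ValueError(
            f"subclustering {target_type!r} needs >= {2 * k_neighbors} cells, found {n_target}"
        )
    sub = counts.subset_cells(mask)
    norm = normalize(sub, cell_size_factors(sub))
    logx = _log_expression(norm)
    s1 = np.asarray(logx.sum(axis=1)).ravel()
    s2 = np.asarray(logx.multiply(logx).sum(axis=1)).ravel()
    var = (s2 - s1**2 / sub.n_cells) / max(sub.n_cells - 1, 1)
    n_variable = int((var > 1e-12).sum())
    if n_hvg > n_variable:
        warnings.warn(f"n_hvg clamped from {n_hvg} to {n_variable} variable genes")
        n_hvg = n_variable
    hvg = select_hvg(norm, n=n_hvg)
    limit = min(len(hvg), sub.n_cells) - 1
    if n_pcs > limit:
        warnings.warn(f"n_pcs clamped from {n_pcs} to {limit}")
        n_pcs = limit
    pcs = pca_embed(norm, hvg, n_pcs=n_pcs)
    assign = louvain_cluster(pcs, k_neighbors=k_neighbors, resolution=resolution, seed=seed, method=method)
    assign.level = f"subcluster-of:{target_type}"
    return assign


def find_markers(norm: NormalizedMatrix, assign: ClusterAssignment) -> pd.DataFrame:
    """One-vs-rest marker statistics per (cluster, gene).

    For each cluster: difference of mean log2(nUMI+1) inside vs outside,
    and the AUROC of the gene separating the cluster from the rest
    (rank-sum formulation, ties by average rank). Rows are sorted by AUROC
    descending within each cluster.
    """
    clusters = assign.cluster_ids
    if len(clusters) < 2:
        raise ValueError("marker discovery needs at least two clusters")
    logx = _log_expression(norm).toarray()  # genes x cells
    labels = assign.labels.reindex(norm.cell_ids).to_numpy()
    ranks = rankdata(logx, axis=1)
    n_cells = logx.shape[1]
    rows = []
    for cl in clusters:
        inmask = labels == cl
        n1 = int(inmask.sum())
        n0 = n_cells - n1
        rank_sum = ranks[:, inmask].sum(axis=1)
        auroc = (rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0)
        mean_in = logx[:, inmask].mean(axis=1)
        mean_out = logx[:, ~inmask].mean(axis=1)
        part = pd.DataFrame(
            {
                "cluster": cl,
                "gene": norm.gene_ids,
                "mean_log_in": mean_in,
                "mean_log_out": mean_out,
                "log_mean_diff": mean_in - mean_out,
                "auroc": auroc,
            }
        )
        rows.append(part.sort_values(["auroc", "gene"], ascending=[False, True], kind="stable"))
    return pd.concat(rows, ignore_index=True)


def flag_doublet_clusters(
    annotation: CellTypeLabel, margin: float | None = None, margin_factor: float = 0.25
) -> list:
    """Flag clusters co-expressing two type signatures.

    A cluster is flagged when its second-best marker-set score comes within
    ``margin`` of its best. With ``margin=None`` the margin is adaptive:
    ``margin_factor`` times the best score's excess over the across-cluster
    median score of that same set. ``margin=inf`` flags every cluster.
    """
    table = annotation.scores
    if table.shape[1] < 2:
        raise ValueError("doublet flagging needs at least two marker sets")
    flagged = []
    for cl in table.index:
        row = table.loc[cl].sort_values(ascending=False)
        best_set, s_best = row.index[0], row.iloc[0]
        s_second = row.iloc[1]
        if margin is not None:
            m = margin
        else:
            # excess of this cluster's best score over the other clusters'
            # typical score for the same set
            others = table.loc[table.index != cl, best_set]
            baseline = float(others.median()) if len(others) else 0.0
            m = margin_factor * (s_best - baseline)
        if s_best - s_second <= m:
            flagged.append(cl)
    return flagged


def cluster_mean_profiles(norm: NormalizedMatrix, assign: ClusterAssignment) -> pd.DataFrame:
    """Mean log2(nUMI+1) per gene within each cluster (genes x clusters)."""
    logx = _log_expression(norm)
    labels = assign.labels.reindex(norm.cell_ids)
    cols = {}
    for cl in assign.cluster_ids:
        mask = (labels == cl).to_numpy()
        cols[cl] = np.asarray(logx[:, mask].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=norm.gene_ids)


def map_to_reference(profile: pd.Series, reference: pd.DataFrame, min_shared: int = 10):
    """Match one expression profile against reference cell-type columns.

    Spearman correlation over the shared genes, per reference column;
    constant columns yield an undefined correlation reported as missing and
    never win. Returns (best_type, ranked table).
    """
    shared = profile.index.intersection(reference.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference (need >= {min_shared})"
        )
    p = profile.loc[shared].to_numpy(dtype=float)
    rows = []
    for ref_type in reference.columns:
        r = reference.loc[shared, ref_type].to_numpy(dtype=float)
        if np.all(r == r[0]) or np.all(p == p[0]):
            rho = np.nan
        else:
            rho = spearmanr(p, r).statistic
        rows.append({"reference_type": ref_type, "spearman": rho})
    table = pd.DataFrame(rows).sort_values(
        "spearman", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)
    valid = table["spearman"].notna()
    best = table.loc[valid, "reference_type"].iloc[0] if valid.any() else None
    return best, table
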