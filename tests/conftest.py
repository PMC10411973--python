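import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gliastate as gs
from gliastate.containers import CountMatrix


def make_counts(array, gene_ids=None, cell_ids=None) -> CountMatrix:
    """Build a CountMatrix from a dense genes x cells array."""
    arr = np.asarray(array)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cells = cell_ids or [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(sp.csr_matrix(arr), pd.Index(genes), pd.Index(cells))


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-sized simulated dataset shared across tests: 4 genotypes,
    10 cell types, planted T-cell expansion and microglial DE."""
    de = {("P301S", "microglia", g): 2.0 for g in range(200, 230)}
    de.update({("P301S", "microglia", g): -2.0 for g in range(230, 260)})
    cfg = gs.default_config(
        target_cells_per_sample=400, n_genes=500, seed=3, de_effects=de
    )
    counts, annot, truth = gs.simulate_dataset(cfg)
    return cfg, counts, annot, truth


@pytest.fixture(scope="session")
def sim_normalized(sim_bundle):
    """QC-filtered and normalized view of the shared dataset."""
    _, counts, annot, truth = sim_bundle
    filtered, report = gs.qc_filter(counts)
    norm = gs.normalize(filtered, gs.cell_size_factors(filtered))
    return filtered, annot.loc[filtered.cell_ids], truth, norm


@pytest.fixture(scope="session")
def four_type_fixture():
    """Four well-separated cell types, no planted DE: the clustering
    recovery benchmark (the planted-DE dataset adds real substructure
    inside microglia, which clustering legitimately resolves)."""
    from gliastate.simdata import SimConfig

    cfg = SimConfig(
        n_groups=2, animals_per_group=3, group_names=("A", "B"),
        cell_types=(("astro", 0.4), ("micro", 0.3), ("oligo", 0.2), ("tcell", 0.1)),
        n_genes=200, marker_genes_per_type=8, mito_gene_count=5,
        target_cells_per_sample=300, seed=42,
    )
    counts, annot, truth = gs.simulate_dataset(cfg)
    return cfg, counts, annot, truth


@pytest.fixture(scope="session")
def sim_clustered(sim_normalized):
    """Clustering + annotation of the shared dataset."""
    filtered, annot, truth, norm = sim_normalized
    hvg = gs.select_hvg(norm, n=200)
    pcs = gs.pca_embed(norm, hvg, n_pcs=20)
    assign = gs.louvain_cluster(pcs, seed=0)
    from gliastate.pipeline import marker_sets_from_gene_names

    sets = marker_sets_from_gene_names(filtered.gene_ids)
    labels = gs.annotate_clusters(assign, norm, sets)
    return assign, labels, sets
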