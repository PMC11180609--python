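import numpy as np
import pytest

import perturbgraph as pg


SMALL_SIM = dict(
    n_genes=30,
    n_pathways=5,
    n_single=12,
    n_double=6,
    planted_per_subtype=1,
    cells_per_condition=15,
    n_control=60,
)


@pytest.fixture(scope="session")
def sim_noisefree():
    """Default-size screen with zero measurement noise (exact means)."""
    return pg.simulate(pg.SimConfig(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def sim_small():
    """A small noisy screen for fast training/evaluation tests."""
    return pg.simulate(pg.SimConfig(seed=0, **SMALL_SIM))


@pytest.fixture(scope="session")
def small_trained():
    """A small screen with a briefly trained model (shared across tests)."""
    ds, mem, truth = pg.simulate(pg.SimConfig(seed=3, **SMALL_SIM))
    split = pg.make_split(ds, mode="combo", fractions=(0.25, 0.1), seed=3)
    train_cells = split.cells(ds, "train")
    g_gene = pg.build_coexpression_graph(ds, 10, 0.1, train_cells=train_cells)
    g_pert = pg.build_perturbation_graph(mem, ds.gene_names, 10)
    model = pg.PerturbModel(
        ds.gene_names, g_gene, g_pert, config=pg.ModelConfig(d=16, seed=3)
    )
    model, history = pg.train(
        model, ds, split, pg.LossConfig(seed=3, epochs=40, node_dropout=0.2)
    )
    return ds, mem, truth, split, g_gene, g_pert, model, history


def make_tiny_model(k=3, d=2, seed=0, edges_gene=(), edges_pert=(), genes=None):
    """A minimal model over k genes with explicit graphs."""
    genes = list(genes or [f"g{i}" for i in range(k)])
    g_gene = pg.GeneGraph(node_ids=genes, edges=list(edges_gene), kind="coexpression")
    g_pert = pg.GeneGraph(
        node_ids=genes, edges=list(edges_pert), kind="perturbation_similarity"
    )
    return pg.PerturbModel(
        genes, g_gene, g_pert, config=pg.ModelConfig(d=d, seed=seed)
    )


@pytest.fixture
def tiny_model_factory():
    return make_tiny_model
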