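"""Forward-pass contracts: locality, composition, decoding, persistence."""

import numpy as np
import pytest

import perturbgraph as pg
from perturbgraph.data import CTRL

from conftest import make_tiny_model


def _identity_mlp(model, name, shift=100.0):
    """Configure a 2-layer ReLU MLP to compute the identity on inputs > -shift."""
    d = model.config.d
    model.params[f"mlp_{name}_w1"].data = np.eye(d)
    model.params[f"mlp_{name}_b1"].data = np.full(d, shift)
    model.params[f"mlp_{name}_w2"].data = np.eye(d)
    model.params[f"mlp_{name}_b2"].data = np.full(d, -shift)


def test_isolated_node_output_depends_only_on_own_embedding():
    m = make_tiny_model(k=3, d=2)  # edgeless graphs
    h0 = m.encode_genes().data.copy()
    # isolated-node contract: output is the self-transform of the embedding
    x = m.params["x_gene"].data
    expected = np.maximum(
        x @ m.params["gnn_gene_self_0"].data + m.params["gnn_gene_bias_0"].data, 0.0
    )
    assert np.allclose(h0, expected, atol=1e-12)
    m.params["x_gene"].data[1] += 10.0  # a non-neighbor of node 0 and 2
    h1 = m.encode_genes().data
    assert np.array_equal(h0[[0, 2]], h1[[0, 2]])


def test_edge_locality():
    m = make_tiny_model(k=3, d=2, edges_gene=[("g0", "g1", 1.0)])
    h0 = m.encode_genes().data.copy()
    m.params["x_gene"].data[1] += 1.0  # g1 is g0's neighbor
    h1 = m.encode_genes().data.copy()
    assert not np.array_equal(h0[0], h1[0])
    m.params["x_gene"].data[2] += 1.0  # g2 is nobody's neighbor
    h2 = m.encode_genes().data
    assert np.array_equal(h1[0], h2[0]) and np.array_equal(h1[1], h2[1])


@pytest.mark.parametrize("which", ["gene", "pert"])
def test_chain_graph_matches_hand_rolled_aggregation(which):
    genes = [f"g{i}" for i in range(10)]
    chain = [(f"g{i}", f"g{i+1}", 1.0) for i in range(9)]
    kw = {"edges_gene": chain} if which == "gene" else {"edges_pert": chain}
    m = make_tiny_model(k=10, d=4, seed=5, genes=genes, **kw)
    x = m.params[f"x_{which}"].data
    w_self = m.params[f"gnn_{which}_self_0"].data
    w_nbr = m.params[f"gnn_{which}_nbr_0"].data
    b = m.params[f"gnn_{which}_bias_0"].data
    # hand-rolled single aggregation step for node 5 (one neighbor: node 6)
    expected = np.maximum(x[5] @ w_self + x[6] @ w_nbr + b, 0.0)
    h = (m.encode_genes() if which == "gene" else m.encode_perturbations()).data
    assert np.allclose(h[5], expected, atol=1e-12)


def test_compose_is_permutation_invariant_bit_exact():
    m = make_tiny_model(k=4, d=3)
    h = m.encode_perturbations()
    a = m.compose_perturbations(["g0", "g2", "g3"], h).data
    b = m.compose_perturbations(["g3", "g0", "g2"], h).data
    assert np.array_equal(a, b)


def test_compose_identity_mlp_returns_single_embedding():
    m = make_tiny_model(k=3, d=2)
    _identity_mlp(m, "compose")
    h = m.encode_perturbations()
    out = m.compose_perturbations({"g1"}, h)
    assert np.allclose(out.data, h.data[1], atol=1e-12)


def test_compose_pre_mlp_sum_is_elementwise_sum():
    m = make_tiny_model(k=4, d=3)
    _identity_mlp(m, "compose")
    h = m.encode_perturbations()
    out = m.compose_perturbations({"g0", "g1", "g2"}, h)
    assert np.allclose(out.data, h.data[0] + h.data[1] + h.data[2], atol=1e-10)


def test_zero_decoder_predicts_control_exactly():
    m = make_tiny_model(k=3, d=2, seed=9)
    m.params["w_cg"].data[:] = 0.0
    m.params["b_cg"].data[:] = 0.0
    g_ctrl = np.array([1.0, 2.0, 0.5])
    res = m.predict({"g0", "g2"}, g_ctrl)
    assert np.array_equal(res.z_hat, np.zeros(3))
    assert np.array_equal(res.g_hat, g_ctrl)


def test_forward_pass_matches_independent_oracle():
    """Enumerated K=3, d=2 model vs a from-scratch numpy forward pass."""
    m = make_tiny_model(
        k=3,
        d=2,
        edges_gene=[("g0", "g1", 0.8)],
        edges_pert=[("g1", "g2", 0.5), ("g1", "g0", 0.25)],
    )
    p = m.params
    # enumerate every parameter with fixed small values
    p["x_gene"].data = np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.6]])
    p["x_pert"].data = np.array([[0.2, 0.1], [-0.3, 0.5], [0.4, -0.1]])
    p["gnn_gene_self_0"].data = np.array([[1.0, 0.5], [-0.5, 1.0]])
    p["gnn_gene_nbr_0"].data = np.array([[0.5, 0.0], [0.0, 0.5]])
    p["gnn_gene_bias_0"].data = np.array([0.05, -0.05])
    p["gnn_pert_self_0"].data = np.array([[0.5, -0.25], [0.25, 0.5]])
    p["gnn_pert_nbr_0"].data = np.array([[1.0, 0.0], [0.5, 1.0]])
    p["gnn_pert_bias_0"].data = np.array([0.0, 0.1])
    for name in ("compose", "postpert"):
        p[f"mlp_{name}_w1"].data = np.array([[1.0, 0.5], [0.0, 1.0]])
        p[f"mlp_{name}_b1"].data = np.array([0.1, 0.2])
        p[f"mlp_{name}_w2"].data = np.array([[0.5, 0.0], [0.5, 1.0]])
        p[f"mlp_{name}_b2"].data = np.array([-0.1, 0.0])
    p["mlp_crossgene_w1"].data = np.array([[0.2, 0.1], [-0.1, 0.3], [0.4, 0.0]])
    p["mlp_crossgene_b1"].data = np.array([0.0, 0.05])
    p["mlp_crossgene_w2"].data = np.array([[1.0, 0.2], [0.0, 1.0]])
    p["mlp_crossgene_b2"].data = np.array([0.1, -0.1])
    p["w_head"].data = np.array([[0.5, 0.5], [1.0, -1.0], [0.25, 0.75]])
    p["b_head"].data = np.array([0.01, 0.02, 0.03])
    p["w_cg"].data = np.array([[1.0, 0.1, 0.2], [0.5, -0.1, 0.3], [0.75, 0.0, -0.2]])
    p["b_cg"].data = np.array([0.0, 0.05, -0.05])
    p["w_unc"].data = np.array([[0.1, 0.0], [0.0, 0.1], [0.1, 0.1]])
    p["b_unc"].data = np.array([-1.0, -1.0, -1.0])

    def mlp(x, w1, b1, w2, b2):
        return np.maximum(x @ w1 + b1, 0.0) @ w2 + b2

    relu = lambda x: np.maximum(x, 0.0)
    # oracle: g0's gene neighbor is g1 (weight 0.8, normalized to 1)
    xg = p["x_gene"].data
    h_gene = relu(xg @ p["gnn_gene_self_0"].data + p["gnn_gene_bias_0"].data)
    h_gene[0] = relu(
        xg[0] @ p["gnn_gene_self_0"].data
        + xg[1] @ p["gnn_gene_nbr_0"].data  # 0.8/0.8 = 1
        + p["gnn_gene_bias_0"].data
    )
    # pert graph: g1 aggregates g2 (2/3) and g0 (1/3)
    xp = p["x_pert"].data
    h_pert = relu(xp @ p["gnn_pert_self_0"].data + p["gnn_pert_bias_0"].data)
    h_pert[1] = relu(
        xp[1] @ p["gnn_pert_self_0"].data
        + ((0.5 / 0.75) * xp[2] + (0.25 / 0.75) * xp[0]) @ p["gnn_pert_nbr_0"].data
        + p["gnn_pert_bias_0"].data
    )
    pert_set = {"g1", "g2"}
    h_p = mlp(
        h_pert[1] + h_pert[2],
        p["mlp_compose_w1"].data, p["mlp_compose_b1"].data,
        p["mlp_compose_w2"].data, p["mlp_compose_b2"].data,
    )
    h_pp = mlp(
        h_gene + h_p,
        p["mlp_postpert_w1"].data, p["mlp_postpert_b1"].data,
        p["mlp_postpert_w2"].data, p["mlp_postpert_b2"].data,
    )
    z = (h_pp * p["w_head"].data).sum(axis=1) + p["b_head"].data
    h_cg = mlp(
        z,
        p["mlp_crossgene_w1"].data, p["mlp_crossgene_b1"].data,
        p["mlp_crossgene_w2"].data, p["mlp_crossgene_b2"].data,
    )
    z_hat = z * p["w_cg"].data[:, 0] + p["w_cg"].data[:, 1:] @ h_cg + p["b_cg"].data
    s = (h_pp * p["w_unc"].data).sum(axis=1) + p["b_unc"].data
    g_ctrl = np.array([1.0, 0.5, 2.0])

    res = m.predict(pert_set, g_ctrl)
    assert np.allclose(res.z_hat, z_hat, atol=1e-10)
    assert np.allclose(res.g_hat, z_hat + g_ctrl, atol=1e-10)
    assert np.allclose(res.s, s, atol=1e-10)


def test_effect_independent_of_control_cell():
    m = make_tiny_model(k=3, d=2, seed=4)
    c1 = np.array([1.0, 1.0, 1.0])
    c2 = np.array([0.5, 2.0, 0.0])
    r1, r2 = m.predict({"g0"}, c1), m.predict({"g0"}, c2)
    assert np.array_equal(r1.z_hat, r2.z_hat)
    assert np.allclose(r1.g_hat - r2.g_hat, c1 - c2)


def test_unseen_perturbation_pathway():
    # g2 has an edge in the perturbation graph: its refined embedding
    # must differ from its raw embedding and the forward pass succeed
    m = make_tiny_model(k=3, d=2, seed=2, edges_pert=[("g2", "g0", 1.0)])
    h = m.encode_perturbations().data
    assert not np.allclose(h[2], m.params["x_pert"].data[2])
    res = m.predict({"g2"}, np.ones(3))
    assert np.all(np.isfinite(res.g_hat))


def test_outputs_finite_for_random_models():
    rng = np.random.default_rng(0)
    for trial in range(100):
        m = make_tiny_model(
            k=5,
            d=4,
            seed=trial,
            edges_gene=[("g0", "g1", float(rng.uniform(-1, 1)))],
            edges_pert=[("g3", "g4", float(rng.uniform(0.01, 1)))],
        )
        for t in m.params.values():
            t.data = rng.normal(scale=2.0, size=t.data.shape)
        n = int(rng.integers(1, 4))
        pert = {f"g{i}" for i in rng.choice(5, size=n, replace=False)}
        res = m.predict(pert, rng.uniform(0, 5, size=5))
        assert np.all(np.isfinite(res.g_hat)) and np.all(np.isfinite(res.s))
        assert np.isfinite(res.uncertainty)


def test_unknown_target_is_fatal_with_name():
    m = make_tiny_model()
    with pytest.raises(KeyError, match="gX"):
        m.predict({"gX"}, np.ones(3))


def test_unmeasured_target_has_pert_embedding_only():
    genes = ["g0", "g1"]
    g = pg.GeneGraph(node_ids=genes, edges=[], kind="coexpression")
    gp = pg.GeneGraph(node_ids=genes + ["tf1"], edges=[], kind="perturbation_similarity")
    m = pg.PerturbModel(
        genes, g, gp, pert_names=genes + ["tf1"], config=pg.ModelConfig(d=2, seed=0)
    )
    assert m.params["x_pert"].data.shape[0] == 3
    assert m.params["x_gene"].data.shape[0] == 2
    res = m.predict({"tf1"}, np.ones(2))
    assert res.g_hat.shape == (2,)


def test_predict_condition_mean_contracts(small_trained):
    ds, _, _, _, _, _, model, _ = small_trained
    cond = next(c for c in ds.conditions if c != CTRL and "+" not in c)
    # n_ctrl = 1 equals a single predict call on that control cell
    s1 = model.predict_condition_mean(cond, ds, n_ctrl=1, seed=5)
    s1b = model.predict_condition_mean(cond, ds, n_ctrl=1, seed=5)
    assert np.array_equal(s1.mean_expression, s1b.mean_expression)  # seeded
    # all controls: mean prediction = z_hat + control mean
    s_all = model.predict_condition_mean(cond, ds)
    res = model.predict(set(cond.split("+")), ds.control_mean())
    assert np.allclose(s_all.mean_expression, res.g_hat, atol=1e-12)
    assert np.allclose(s_all.mean_delta, res.z_hat, atol=1e-12)


def test_checkpoint_roundtrip(tmp_path, small_trained):
    ds, _, _, _, _, _, model, _ = small_trained
    path = tmp_path / "ckpt"
    model.save(path)
    back = pg.PerturbModel.load(path)
    cond = next(c for c in ds.conditions if c != CTRL)
    a = model.predict(set(cond.split("+")), ds.control_mean())
    b = back.predict(set(cond.split("+")), ds.control_mean())
    assert np.array_equal(a.g_hat, b.g_hat)


def test_checkpoint_gene_hash_verified(tmp_path, small_trained):
    import json

    _, _, _, _, _, _, model, _ = small_trained
    path = tmp_path / "ckpt"
    model.save(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    sidecar["gene_names"][0] = "TAMPERED"
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    with pytest.raises(ValueError, match="hash"):
        pg.PerturbModel.load(path)
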