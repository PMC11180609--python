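"""Loss definitions, gradients and the optimization loop."""

import numpy as np
import pytest

import perturbgraph as pg
from perturbgraph.autodiff import Tensor
from perturbgraph.training import LossConfig, autofocus_loss, direction_loss, uncertainty_loss

from conftest import make_tiny_model


# -- loss values ---------------------------------------------------------------

def test_autofocus_gamma0_is_mse():
    rng = np.random.default_rng(0)
    for _ in range(20):
        pred, true = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        assert np.isclose(
            autofocus_loss(pred, true, gamma=0.0).item(),
            np.mean((pred - true) ** 2),
            atol=1e-12,
        )


def test_autofocus_direct_formula():
    # one perturbation, one cell, K=2, g=(1,0), ghat=(0,0)
    g, ghat = np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])
    assert autofocus_loss(ghat, g, gamma=0.0).item() == pytest.approx(0.5)
    # gamma=1 with the magnitude convention: mean |e|^3 = 0.5
    assert autofocus_loss(ghat, g, gamma=1.0).item() == pytest.approx(0.5)


def test_autofocus_groups_weight_perturbations_equally():
    # two perturbations with different cell counts get equal weight
    a_pred, a_true = np.zeros((1, 2)), np.ones((1, 2))
    b_pred, b_true = np.zeros((3, 2)), np.zeros((3, 2))
    loss = autofocus_loss([a_pred, b_pred], [a_true, b_true], gamma=0.0)
    assert loss.item() == pytest.approx(0.5)  # (1 + 0) / 2


@pytest.mark.parametrize(
    "true_delta,pred_delta,expected",
    [(1.0, 2.0, 0.0), (1.0, -1.0, 4.0), (0.0, 1.0, 1.0), (-1.0, 0.0, 1.0)],
)
def test_direction_loss_per_gene_terms(true_delta, pred_delta, expected):
    ctrl = np.array([1.0])
    loss = direction_loss(
        np.array([[ctrl[0] + pred_delta]]), np.array([[ctrl[0] + true_delta]]), ctrl
    )
    assert loss.item() == pytest.approx(expected)


def test_direction_loss_zero_iff_signs_match():
    rng = np.random.default_rng(1)
    ctrl = rng.uniform(1, 2, size=8)
    true = ctrl + rng.choice([-0.5, 0.5], size=(3, 8))
    pred = ctrl + np.sign(true - ctrl) * rng.uniform(0.1, 2.0, size=(3, 8))
    assert direction_loss(pred, true, ctrl).item() == 0.0
    pred[0, 0] = ctrl[0] - (true[0, 0] - ctrl[0])
    assert direction_loss(pred, true, ctrl).item() > 0.0


def test_uncertainty_loss_reduces_to_autofocus_at_s_zero():
    rng = np.random.default_rng(2)
    pred, true = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
    s = np.zeros((5, 4))
    full = uncertainty_loss(pred, true, s, gamma=1.0)
    bare = uncertainty_loss(pred, true, s, gamma=1.0, include_regularizer=False)
    auto = autofocus_loss(pred, true, gamma=1.0)
    assert full.item() == pytest.approx(auto.item(), abs=1e-12)  # regularizer = mean(0)
    assert bare.item() == pytest.approx(auto.item(), abs=1e-12)


def test_uncertainty_loss_single_term_and_monotonicity():
    # single term, s = ln 2, squared error 1, gamma=0 -> 0.5 before regularizer
    pred, true = np.array([[0.0]]), np.array([[1.0]])
    s = np.array([[np.log(2.0)]])
    bare = uncertainty_loss(pred, true, s, gamma=0.0, include_regularizer=False)
    assert bare.item() == pytest.approx(0.5)
    lower = uncertainty_loss(
        pred, true, np.array([[1.0]]), gamma=0.0, include_regularizer=False
    )
    higher = uncertainty_loss(
        pred, true, np.array([[0.5]]), gamma=0.0, include_regularizer=False
    )
    assert lower.item() < higher.item()


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(gamma=-0.1)
    with pytest.raises(ValueError):
        LossConfig(lam=-1.0)


# -- gradients through the model ----------------------------------------------

def _loss_through_model(model, which, param_name, data):
    g_true, g_ctrl = data

    def value():
        z_hat, s = model.forward_batch([frozenset({"g0"}), frozenset({"g1", "g2"})])
        g_hat = z_hat + Tensor(np.broadcast_to(g_ctrl, z_hat.shape).copy())
        if which == "autofocus":
            return autofocus_loss(g_hat, g_true, gamma=1.0)
        if which == "direction":
            return direction_loss(g_hat, g_true, g_ctrl)
        s_t = s
        return uncertainty_loss(g_hat, g_true, s_t, gamma=1.0)

    return value


@pytest.mark.parametrize("which", ["autofocus", "direction", "uncertainty"])
@pytest.mark.parametrize("param_name", ["x_pert", "w_head", "mlp_postpert_w1", "w_unc"])
def test_loss_gradients_match_finite_differences(which, param_name):
    model = make_tiny_model(
        k=3, d=2, seed=8,
        edges_gene=[("g0", "g1", 0.5)], edges_pert=[("g1", "g2", 1.0)],
    )
    rng = np.random.default_rng(3)
    g_true = rng.uniform(0.5, 2.0, size=(2, 3))
    g_ctrl = rng.uniform(0.5, 2.0, size=3)
    value = _loss_through_model(model, which, param_name, (g_true, g_ctrl))
    loss = value()
    for p in model.parameters():
        p.grad = None
    loss.backward()
    param = model.params[param_name]
    auto_grad = param.grad if param.grad is not None else np.zeros_like(param.data)
    flat_idx = [(0, 0), (param.data.shape[0] - 1, param.data.shape[1] - 1)]
    for idx in flat_idx:
        eps = 1e-6
        orig = param.data[idx]
        param.data[idx] = orig + eps
        up = value().item()
        param.data[idx] = orig - eps
        down = value().item()
        param.data[idx] = orig
        num = (up - down) / (2 * eps)
        scale = max(abs(num), abs(auto_grad[idx]), 1e-6)
        assert abs(auto_grad[idx] - num) / scale < 1e-4


# -- the training loop ---------------------------------------------------------

def test_training_strictly_decreases_loss(small_trained):
    _, _, _, _, _, _, _, history = small_trained
    assert history[-1]["train_loss"] < history[0]["train_loss"]


def test_training_is_deterministic(sim_small):
    ds, mem, _ = sim_small
    split = pg.make_split(ds, mode="single", fractions=(0.25, 0.1), seed=0)
    tc = split.cells(ds, "train")
    g_gene = pg.build_coexpression_graph(ds, 5, 0.1, train_cells=tc)
    g_pert = pg.build_perturbation_graph(mem, ds.gene_names, 5)

    def run():
        m = pg.PerturbModel(ds.gene_names, g_gene, g_pert, config=pg.ModelConfig(d=8, seed=1))
        m, hist = pg.train(m, ds, split, pg.LossConfig(seed=1, epochs=5))
        return m, hist

    m1, h1 = run()
    m2, h2 = run()
    assert h1 == h2
    for k in m1.params:
        assert np.array_equal(m1.params[k].data, m2.params[k].data)


def test_empty_training_split_fatal(sim_small):
    ds, mem, _ = sim_small
    split = pg.SplitPlan(train=["ctrl"], val=[], test=ds.conditions[:1], test_class={})
    g_gene = pg.build_coexpression_graph(ds, 5, 0.1)
    g_pert = pg.build_perturbation_graph(mem, ds.gene_names, 5)
    m = pg.PerturbModel(ds.gene_names, g_gene, g_pert, config=pg.ModelConfig(d=8))
    with pytest.raises(ValueError, match="empty training split"):
        pg.train(m, ds, split, pg.LossConfig(epochs=1))


def test_gamma0_lam0_training_matches_mse_objective(sim_small):
    """With gamma=0 and lam=0 the optimized batch loss is plain MSE."""
    ds, mem, _ = sim_small
    split = pg.make_split(ds, mode="single", fractions=(0.25, 0.1), seed=0)
    g_gene = pg.build_coexpression_graph(ds, 5, 0.1, train_cells=split.cells(ds, "train"))
    g_pert = pg.build_perturbation_graph(mem, ds.gene_names, 5)
    m = pg.PerturbModel(ds.gene_names, g_gene, g_pert, config=pg.ModelConfig(d=8, seed=0))
    conds = [c for c in split.train if c != "ctrl"][:4]
    sets = [frozenset(c.split("+")) for c in conds]
    z_hat, _ = m.forward_batch(sets)
    rng = np.random.default_rng(0)
    cells = np.stack([rng.choice(ds.cells_of(c), size=3) for c in conds])
    ctrls = rng.choice(ds.cells_of("ctrl"), size=cells.shape)
    g_hat = z_hat.data[:, None, :] + ds.expression[ctrls]
    g_true = ds.expression[cells]
    ours = autofocus_loss(
        [Tensor(g_hat[i]) for i in range(len(conds))],
        [Tensor(g_true[i]) for i in range(len(conds))],
        gamma=0.0,
    ).item()
    independent = np.mean([np.mean((g_hat[i] - g_true[i]) ** 2) for i in range(len(conds))])
    assert ours == pytest.approx(independent, abs=1e-12)
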