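"""Loss functions and the end-to-end optimization loop.

Three losses drive training, each averaged first over genes, then over a
perturbation's cells, then over the perturbations of the minibatch:

* **autofocus**: |g − ĝ|^(2+γ). Raising the exponent above 2 makes the
  few strongly differentially expressed genes dominate the objective.
  The magnitude convention keeps the loss non-negative for any γ ≥ 0
  (raw signed powers are ill-defined for fractional exponents and
  sign-canceling for odd ones); γ = 0 recovers plain MSE.
* **direction**: [sign(g − g_ctrl) − sign(ĝ − g_ctrl)]², penalizing a
  predicted change in the wrong direction relative to control; each
  per-gene term is 0, 1 or 4, and the term is 0 exactly when the signs
  match. Being sign-based it is piecewise constant, so it acts as a
  value-level regularizer rather than a gradient source.
* **uncertainty**: exp(−s)·|g − ĝ|^(2+γ) plus a mean(s) regularizer —
  the heteroscedastic Gaussian-likelihood trade-off that teaches the
  per-gene log-variance s to track prediction error. Without the
  regularizer the objective is unbounded below in s.

The total objective is L_autofocus + λ·L_direction (or, with the
uncertainty head enabled, L_unc + λ·L_direction). Minibatches sample
perturbation conditions, then cells within each condition, and pair
every perturbed cell with a randomly sampled control cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as adf
from .autodiff import Adam, Tensor
from .data import CTRL, PerturbDataset, SplitPlan, condition_targets
from .model import PerturbModel

__all__ = [
    "LossConfig",
    "autofocus_loss",
    "direction_loss",
    "uncertainty_loss",
    "train",
]


@dataclass
class LossConfig:
    """Training hyperparameters.

    gamma : autofocus exponent offset (error power is 2 + gamma).
    lam : weight λ of the direction-aware loss.
    use_uncertainty : optimize the heteroscedastic objective instead of
        the plain autofocus loss.
    cells_per_condition : cells sampled per condition per step; each is
        paired with a random control cell.
    node_dropout : probability of zeroing a perturbation node's raw
        embedding for a training step. Dropped nodes must be predicted
        from their pathway-graph neighbors alone, which is exactly the
        situation of a never-perturbed gene at test time.
    patience : early-stopping patience on the validation loss (epochs);
        None disables early stopping.
    """

    gamma: float = 1.0
    lam: float = 0.1
    use_uncertainty: bool = False
    lr: float = 1e-3
    epochs: int = 600
    node_dropout: float = 0.3
    batch_conditions: int | None = None  # None = all train conditions per step
    cells_per_condition: int = 8
    patience: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lam must be non-negative")


def _as_groups(x) -> list:
    """Normalize input to a list of per-perturbation Tensors."""
    if isinstance(x, (list, tuple)):
        return [t if isinstance(t, Tensor) else Tensor(t) for t in x]
    return [x if isinstance(x, Tensor) else Tensor(x)]


def autofocus_loss(pred, true, gamma: float = 1.0):
    """Mean |g − ĝ|^(2+γ), averaged per perturbation then across them.

    ``pred`` / ``true`` are cells × genes arrays for one perturbation,
    or lists of such arrays (one entry per perturbation in the batch).
    Returns a scalar Tensor.
    """
    preds, trues = _as_groups(pred), _as_groups(true)
    total = None
    for p, t in zip(preds, trues):
        term = adf.abs_power(t - p, 2.0 + gamma).mean()
        total = term if total is None else total + term
    return total / len(preds)


def direction_loss(pred, true, g_ctrl):
    """Mean squared sign mismatch of the delta over control.

    Per-gene terms are (sign(g−g_ctrl) − sign(ĝ−g_ctrl))² ∈ {0, 1, 4},
    with sign(0) = 0; the loss is zero iff every predicted delta shares
    the true delta's sign.
    """
    preds, trues = _as_groups(pred), _as_groups(true)
    ctrl = g_ctrl if isinstance(g_ctrl, Tensor) else Tensor(g_ctrl)
    total = None
    for p, t in zip(preds, trues):
        d = adf.sign(t - ctrl) - adf.sign(p - ctrl)
        term = (d * d).mean()
        total = term if total is None else total + term
    return total / len(preds)


def uncertainty_loss(pred, true, s, gamma: float = 1.0, include_regularizer: bool = True):
    """Heteroscedastic autofocus loss exp(−s)·|g − ĝ|^(2+γ) (+ mean(s)).

    With s = 0 everywhere this equals the autofocus loss plus the (zero)
    regularizer; larger s down-weights a gene's error monotonically.
    """
    preds, trues, ss = _as_groups(pred), _as_groups(true), _as_groups(s)
    total, reg = None, None
    for p, t, si in zip(preds, trues, ss):
        term = (adf.exp(-si) * adf.abs_power(t - p, 2.0 + gamma)).mean()
        r = si.mean()
        total = term if total is None else total + term
        reg = r if reg is None else reg + r
    loss = total / len(preds)
    if include_regularizer:
        loss = loss + reg / len(preds)
    return loss


# -- optimization loop ---------------------------------------------------------

def _sample_batch(rng, cond_cells, ctrl_cells, conds, c_per):
    """Sample cells per condition and pair each with a random control cell."""
    cell_idx = np.stack(
        [rng.choice(cond_cells[c], size=c_per, replace=len(cond_cells[c]) < c_per) for c in conds]
    )
    ctrl_idx = rng.choice(ctrl_cells, size=cell_idx.shape, replace=True)
    return cell_idx, ctrl_idx


def _batch_loss(model, ds, conds, cell_idx, ctrl_idx, cfg, ctrl_mean, embedding_mask=None):
    sets = [condition_targets(c) for c in conds]
    z_hat, s = model.forward_batch(sets, embedding_mask)
    t_n, c_per = cell_idx.shape
    k = ds.n_genes
    g_true = Tensor(ds.expression[cell_idx])  # (T, C, K)
    g_ctrl_cells = ds.expression[ctrl_idx]  # (T, C, K)
    g_hat = z_hat.reshape(t_n, 1, k) + Tensor(g_ctrl_cells)
    # uniform cells per condition makes the flat mean equal the grouped mean
    l_dir = direction_loss(g_hat, g_true, ctrl_mean)
    if cfg.use_uncertainty:
        s3 = s.reshape(t_n, 1, k) + Tensor(np.zeros((t_n, c_per, k)))
        l_fit = uncertainty_loss(g_hat, g_true, s3, cfg.gamma)
    else:
        l_fit = autofocus_loss(g_hat, g_true, cfg.gamma)
    total = l_fit + cfg.lam * l_dir
    return total, l_fit, l_dir


def train(
    model: PerturbModel,
    ds: PerturbDataset,
    split: SplitPlan,
    config: LossConfig | None = None,
) -> tuple:
    """Stochastic-gradient training; returns (model, history).

    Seeded and deterministic on a single thread; ``history`` is one dict
    per epoch with train/validation losses. Validation-based early
    stopping restores the best parameters.
    """
    cfg = config or LossConfig()
    train_conds = [c for c in split.train if c != CTRL]
    if not train_conds:
        raise ValueError("empty training split")
    val_conds = [c for c in split.val if c != CTRL]
    cond_cells = {c: ds.cells_of(c) for c in train_conds + val_conds}
    ctrl_cells = ds.cells_of(CTRL)
    ctrl_mean = ds.control_mean()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    batch_size = cfg.batch_conditions or len(train_conds)
    history = []
    best_val, best_params, since_best = np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_conds))
        ep_total = ep_fit = ep_dir = 0.0
        n_batches = 0
        for start in range(0, len(order), batch_size):
            conds = [train_conds[i] for i in order[start : start + batch_size]]
            cell_idx, ctrl_idx = _sample_batch(
                rng, cond_cells, ctrl_cells, conds, cfg.cells_per_condition
            )
            mask = None
            if cfg.node_dropout > 0:
                mask = (rng.random(len(model.pert_names)) >= cfg.node_dropout).astype(float)
            total, l_fit, l_dir = _batch_loss(
                model, ds, conds, cell_idx, ctrl_idx, cfg, ctrl_mean, mask
            )
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_total += total.item()
            ep_fit += l_fit.item()
            ep_dir += l_dir.item()
            n_batches += 1
        record = {
            "epoch": epoch,
            "train_loss": ep_total / n_batches,
            "train_fit": ep_fit / n_batches,
            "train_direction": ep_dir / n_batches,
        }
        if val_conds:
            cell_idx, ctrl_idx = _sample_batch(
                np.random.default_rng(cfg.seed + 1), cond_cells, ctrl_cells, val_conds,
                cfg.cells_per_condition,
            )
            val_total, _, _ = _batch_loss(model, ds, val_conds, cell_idx, ctrl_idx, cfg, ctrl_mean)
            record["val_loss"] = val_total.item()
            if record["val_loss"] < best_val - 1e-9:
                best_val = record["val_loss"]
                best_params = {k: v.data.copy() for k, v in model.params.items()}
                since_best = 0
            else:
                since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                history.append(record)
                break
        history.append(record)
    if best_params is not None:
        for k, v in model.params.items():
            v.data = best_params[k]
    return model, history
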