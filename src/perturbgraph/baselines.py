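"""Non-deep reference predictors.

Three baselines bracket the prediction task:

* **no-perturbation** — predicts the control mean for every condition
  (zero effect); the denominator of every normalized error metric;
* **additive** — predicts a two-gene condition as the sum of the two
  measured single-gene deltas, the naive null that genetic-interaction
  scoring deviates from;
* **linear GRN propagation** — infers a sparse linear gene regulatory
  network from training cells (per-target ridge regression, top-q
  coefficients kept) and linearly propagates an initial expression
  shift on the perturbed targets through the network for p steps, in
  the shift-then-propagate style of regulatory-network simulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .data import (
    CTRL,
    ConditionSummary,
    PerturbDataset,
    canonical_condition,
    condition_targets,
    rank_de_genes,
)

__all__ = [
    "no_perturbation_baseline",
    "additive_baseline",
    "LinearGRN",
    "infer_grn",
    "grn_linear_baseline",
]


def _summary(ds: PerturbDataset, key: str, delta: np.ndarray, n_cells: int = 0) -> ConditionSummary:
    mean = ds.control_mean() + delta
    return ConditionSummary(
        condition_key=key,
        mean_expression=mean,
        mean_delta=delta,
        n_cells=n_cells,
        top_de_genes=rank_de_genes(delta, ds.gene_names),
        gene_names=list(ds.gene_names),
    )


def no_perturbation_baseline(ds: PerturbDataset, condition) -> ConditionSummary:
    """Predict no change: the control mean, whatever the perturbation."""
    key = canonical_condition(condition)
    return _summary(ds, key, np.zeros(ds.n_genes))


def additive_baseline(summary_a: ConditionSummary, summary_b: ConditionSummary) -> ConditionSummary:
    """Predicted combo delta = sum of the two single-gene deltas."""
    delta = summary_a.mean_delta + summary_b.mean_delta
    key = canonical_condition(
        condition_targets(summary_a.condition_key) | condition_targets(summary_b.condition_key)
    )
    ctrl_mean = summary_a.mean_expression - summary_a.mean_delta
    gene_order = summary_a.gene_names or [
        summary_a.top_de_genes[i]
        for i in np.argsort(
            np.lexsort((np.arange(len(delta)), -np.abs(summary_a.mean_delta)))
        )
    ]
    return ConditionSummary(
        condition_key=key,
        mean_expression=ctrl_mean + delta,
        mean_delta=delta,
        n_cells=0,
        top_de_genes=rank_de_genes(delta, gene_order),
        gene_names=gene_order,
    )


@dataclass
class LinearGRN:
    """Sparse signed gene–gene influence matrix for linear propagation.

    ``weights[u, j]`` is the inferred influence of gene j on gene u; the
    diagonal is zero (a gene does not regulate itself in the linear
    propagation).
    """

    weights: np.ndarray  # (K, K)
    steps: int = 3

    def propagate(self, shift: np.ndarray) -> np.ndarray:
        """(I + W + … + W^steps) @ shift, truncated linear propagation."""
        delta = shift.copy()
        term = shift.copy()
        for _ in range(self.steps):
            term = self.weights @ term
            delta = delta + term
        return delta


def infer_grn(
    ds: PerturbDataset,
    train_cells: np.ndarray | None = None,
    top_q: int = 20,
    alpha: float = 1.0,
    steps: int = 3,
) -> LinearGRN:
    """Per-target ridge regression of each gene on all others; keep the
    ``top_q`` largest-magnitude coefficients per target gene."""
    x = ds.expression if train_cells is None else ds.expression[np.asarray(train_cells)]
    k = ds.n_genes
    w = np.zeros((k, k))
    for u in range(k):
        others = np.delete(np.arange(k), u)
        model = Ridge(alpha=alpha, fit_intercept=True)
        model.fit(x[:, others], x[:, u])
        coefs = model.coef_
        if top_q < coefs.size:
            cut = np.argpartition(np.abs(coefs), -top_q)[-top_q:]
            keep = np.zeros_like(coefs)
            keep[cut] = coefs[cut]
            coefs = keep
        w[u, others] = coefs
    return LinearGRN(weights=w, steps=steps)


def grn_linear_baseline(
    ds: PerturbDataset,
    condition,
    grn: LinearGRN,
    shift_sd: float = 1.0,
    train_cells: np.ndarray | None = None,
) -> ConditionSummary:
    """Shift the perturbed targets, propagate linearly, add to control mean.

    The initial shift on each measured target is ``shift_sd`` training
    standard deviations of that gene (positive for activation screens;
    pass a negative ``shift_sd`` for knockdowns). Unmeasured targets
    contribute no shift.
    """
    key = canonical_condition(condition)
    x = ds.expression if train_cells is None else ds.expression[np.asarray(train_cells)]
    sd = x.std(axis=0)
    shift = np.zeros(ds.n_genes)
    for target in condition_targets(key):
        if target in ds.gene_names:
            shift[ds.gene_index(target)] = shift_sd * sd[ds.gene_index(target)]
        else:
            import warnings

            warnings.warn(f"target {target!r} not measured; zero initial shift", stacklevel=2)
    delta = grn.propagate(shift)
    return _summary(ds, key, delta)
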