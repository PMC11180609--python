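"""Simulation-based recovery benchmarks.

These drive the package's self-validation: train on a synthetic screen
with known ground truth, then measure how well held-out perturbation
effects are recovered, against (a) the no-perturbation baseline and
(b) an ablation that randomizes the perturbation-similarity graph's
edges (destroying the inductive bias while keeping capacity equal).
"""

from __future__ import annotations

import numpy as np

from .baselines import no_perturbation_baseline
from .data import CTRL, condition_targets, make_split
from .graphs import build_coexpression_graph, build_perturbation_graph, shuffle_edges
from .model import ModelConfig, PerturbModel
from .simulate import SimConfig, simulate, truth_metrics
from .training import LossConfig, train

__all__ = ["heldout_single_recovery", "gi_subtype_recovery"]


def heldout_single_recovery(
    seed: int,
    sim_config: SimConfig | None = None,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    with_ablation: bool = True,
) -> dict:
    """Train on a simulated screen and score held-out single perturbations.

    Holds out 25% of single-gene conditions, trains the full model and
    (optionally) an edge-shuffled-perturbation-graph ablation with the
    same seeds, and reports the mean Pearson correlation between the
    predicted and true effect vectors over held-out singles that have at
    least one perturbation-graph neighbor among the training targets.
    """
    sim_cfg = sim_config or SimConfig(seed=seed)
    ds, membership, truth = simulate(sim_cfg)
    split = make_split(ds, mode="single", fractions=(0.25, 0.1), seed=seed)
    train_cells = split.cells(ds, "train")
    g_gene = build_coexpression_graph(ds, 20, 0.1, train_cells=train_cells)
    g_pert = build_perturbation_graph(membership, ds.gene_names, 20)
    train_targets = split.train_targets()
    eligible = [
        c
        for c in split.test
        if len(condition_targets(c)) == 1 and set(g_pert.neighbors(c)) & train_targets
    ]

    def run(graph_pert):
        mcfg = model_config or ModelConfig(seed=seed)
        model = PerturbModel(ds.gene_names, g_gene, graph_pert, config=mcfg)
        lcfg = loss_config or LossConfig(seed=seed)
        model, _ = train(model, ds, split, lcfg)
        preds = {c: model.predict_condition_mean(c, ds).mean_delta for c in eligible}
        return float(truth_metrics(truth, preds)["pearson_delta"].mean())

    out = {
        "seed": seed,
        "n_eligible": len(eligible),
        "model": run(g_pert),
        "baseline": float(
            truth_metrics(
                truth, {c: no_perturbation_baseline(ds, c).mean_delta for c in eligible}
            )["pearson_delta"].mean()
        ),
    }
    if with_ablation:
        out["shuffled_graph"] = run(shuffle_edges(g_pert, seed))
    return out


def gi_subtype_recovery(seed: int, k: int = 5, noise_sd: float = 0.0) -> dict:
    """Score measured synthetic profiles and rank planted interaction pairs.

    Validates the scoring pipeline independently of any trained model:
    for each planted subtype, precision@k of that subtype's own score
    against the planted pairs.
    """
    from .data import summarize_condition
    from .gi import GI_SUBTYPES, score_pairs

    ds, _, truth = simulate(SimConfig(seed=seed, noise_sd=noise_sd))
    summaries = {c: summarize_condition(ds, c) for c in ds.conditions if c != CTRL}
    pairs = [tuple(key.split("+")) for key in truth.double_effects]
    table = score_pairs(summaries, pairs)
    out = {}
    for subtype in GI_SUBTYPES:
        scores = table.scores(subtype)
        top = sorted(scores, key=lambda p: (-scores[p], p))[:k]
        planted = set(truth.planted[subtype])
        out[subtype] = len(set(top) & planted) / k
    return out
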