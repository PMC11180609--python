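"""Prediction metrics and per-split evaluation reports.

All metrics compare a predicted condition summary against the measured
one. Because most genes barely move under any perturbation, the error
metrics concentrate on the measured condition's top-20 differentially
expressed genes (always determined from true data, never from the
prediction, except for the DE-set Jaccard where the predicted DE set is
by definition model-derived):

* ``mse_top_de`` — MSE of postperturbation expression on the truth's
  top-k DE genes, reported both raw and normalized per condition to the
  no-perturbation baseline (so the baseline itself scores exactly 1);
* ``pearson_delta`` — Pearson correlation of predicted vs true mean
  delta over all genes;
* ``direction_flip_fraction`` — fraction of top-k DE genes whose
  predicted delta points the wrong way;
* ``jaccard_de`` — overlap of predicted and true top-k DE gene sets.

Reports are stratified by generalization class (unseen single, 0/1/2-
of-2-unseen combos) and aggregated as mean ± 1.96·SEM (normal 95% CI)
across conditions; :func:`aggregate_reports` pools reports from models
trained on different splits/seeds the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ConditionSummary, PerturbDataset, SplitPlan, summarize_condition
from .baselines import no_perturbation_baseline

__all__ = [
    "mse_top_de",
    "pearson_delta",
    "direction_flip_fraction",
    "jaccard_de",
    "evaluate",
    "MetricReport",
    "aggregate_reports",
]


def _top_idx(truth: ConditionSummary, k: int) -> np.ndarray:
    if k > len(truth.mean_delta):
        raise ValueError(f"k={k} exceeds the number of measured genes")
    return np.array([truth.gene_column(g) for g in truth.top_k(k)], dtype=int)


def mse_top_de(pred: ConditionSummary, truth: ConditionSummary, k: int = 20) -> float:
    """MSE of postperturbation expression over truth's top-k DE genes."""
    idx = _top_idx(truth, k)
    diff = pred.mean_expression[idx] - truth.mean_expression[idx]
    return float(np.mean(diff**2))


def pearson_delta(pred: ConditionSummary, truth: ConditionSummary) -> float:
    """Pearson correlation of mean deltas over all genes (0 if degenerate)."""
    a, b = pred.mean_delta, truth.mean_delta
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def direction_flip_fraction(pred: ConditionSummary, truth: ConditionSummary, k: int = 20) -> float:
    """Fraction of truth's top-k DE genes whose predicted delta has the
    wrong sign (sign(0) counts as a flip against a nonzero truth)."""
    idx = _top_idx(truth, k)
    return float(np.mean(np.sign(pred.mean_delta[idx]) != np.sign(truth.mean_delta[idx])))


def jaccard_de(pred: ConditionSummary, truth: ConditionSummary, k: int = 20) -> float:
    """Jaccard index of predicted vs true top-k DE gene sets."""
    a, b = set(pred.top_k(k)), set(truth.top_k(k))
    return len(a & b) / len(a | b) if (a | b) else 0.0


@dataclass
class MetricReport:
    """Per-condition metric table plus class-stratified aggregates."""

    per_condition: pd.DataFrame
    k: int = 20

    METRICS = (
        "mse_top20",
        "mse_top20_normalized",
        "pearson_delta_allgenes",
        "direction_flip_fraction",
        "jaccard_de",
    )

    def aggregate(self) -> pd.DataFrame:
        """Mean and 95% CI (1.96·SEM) per metric, overall and per class."""
        frames = []
        groups = [("all", self.per_condition)] + [
            (cls, g) for cls, g in self.per_condition.groupby("class")
        ]
        for name, g in groups:
            for metric in self.METRICS:
                vals = g[metric].to_numpy(dtype=float)
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                frames.append(
                    {
                        "stratum": name,
                        "metric": metric,
                        "mean": vals.mean(),
                        "ci95": 1.96 * sem,
                        "n": len(vals),
                    }
                )
        return pd.DataFrame(frames)

    def to_tsv(self, path) -> None:
        self.per_condition.to_csv(path, sep="\t", index=False)


def evaluate(
    predict_fn,
    ds: PerturbDataset,
    split: SplitPlan,
    k: int = 20,
) -> MetricReport:
    """Score a predictor on every held-out test condition.

    ``predict_fn(condition_key) -> ConditionSummary`` may wrap the
    trained model or any baseline. Normalized MSE divides by the
    no-perturbation baseline per condition.
    """
    if not split.test:
        raise ValueError("empty test split")
    rows = []
    for cond in split.test:
        truth = summarize_condition(ds, cond)
        pred = predict_fn(cond)
        base = no_perturbation_baseline(ds, cond)
        mse = mse_top_de(pred, truth, k)
        mse_base = mse_top_de(base, truth, k)
        rows.append(
            {
                "condition": cond,
                "class": split.test_class[cond],
                "mse_top20": mse,
                "mse_top20_normalized": mse / mse_base if mse_base > 0 else np.nan,
                "pearson_delta_allgenes": pearson_delta(pred, truth),
                "direction_flip_fraction": direction_flip_fraction(pred, truth, k),
                "jaccard_de": jaccard_de(pred, truth, k),
            }
        )
    return MetricReport(per_condition=pd.DataFrame(rows), k=k)


def aggregate_reports(reports: list) -> pd.DataFrame:
    """Pool several MetricReports (e.g. five training splits): mean and
    1.96·SEM across the per-report means, overall and per class."""
    per_seed = []
    for i, rep in enumerate(reports):
        agg = rep.aggregate()
        agg["seed"] = i
        per_seed.append(agg)
    stacked = pd.concat(per_seed, ignore_index=True)
    out = []
    for (stratum, metric), g in stacked.groupby(["stratum", "metric"]):
        vals = g["mean"].to_numpy(dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out.append(
            {
                "stratum": stratum,
                "metric": metric,
                "mean": vals.mean(),
                "ci95": 1.96 * sem,
                "n_reports": len(vals),
            }
        )
    return pd.DataFrame(out)
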