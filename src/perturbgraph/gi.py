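"""Genetic-interaction scoring and rank-based benchmarking.

A two-gene perturbation deviates from the additive null when the genes
interact. Following the regression framework of combinatorial CRISPRa
screens, each pair (a, b) is characterized by a least-squares fit of the
combo delta on the two single deltas,

    delta_ab ≈ c_a · delta_a + c_b · delta_b,

restricted to the union of the three conditions' top-20 DE genes (the
genes where anything happens). The fitted coefficients and the fit
quality span the interaction axes:

* magnitude ‖(c_a, c_b)‖₂ — high ⇒ **synergy**, low ⇒ **suppression**;
* model fit corr(fitted, actual) — poor linear fit ⇒ **neomorphism**
  (the combo phenotype is not in the span of the singles);
* similarity corr(delta_a, delta_b) with sub-additive magnitude ⇒
  **redundancy** (interchangeable singles, combo under-delivers);
* dominance ‖c_a‖ vs ‖c_b‖ imbalance ⇒ **epistasis** (one gene masks
  the other).

All scores are monotone (higher = more of the subtype); threshold-based
truth calls default to each score's upper decile and every threshold is
config-exposed. Ranking quality is reported as precision@k, top-k
accuracy and a precision–recall curve, with a 1,000-draw random-ranking
null for calibration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConditionSummary, PerturbDataset, canonical_condition
from .model import PerturbModel

__all__ = [
    "FitResult",
    "GIScoreTable",
    "RankingBenchmark",
    "fit_combo_model",
    "de_union_mask",
    "score_subtypes",
    "score_pairs",
    "benchmark_ranking",
    "random_ranking_precision",
    "gi_map",
    "GI_SUBTYPES",
]

GI_SUBTYPES = ("synergy", "suppression", "neomorphism", "redundancy", "epistasis")

COLLINEARITY_LIMIT = 0.995  # |corr| of singles above which the fit is degenerate
ZERO_NORM_LIMIT = 1e-12


@dataclass
class FitResult:
    """Least-squares decomposition of a combo delta onto its singles."""

    c_a: float
    c_b: float
    fit_corr: float
    similarity: float  # corr(delta_a, delta_b) on the mask
    degenerate: bool = False


def _masked_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fit_combo_model(
    delta_a: np.ndarray,
    delta_b: np.ndarray,
    delta_ab: np.ndarray,
    gene_mask: np.ndarray | None = None,
) -> FitResult:
    """Fit delta_ab ≈ c_a·delta_a + c_b·delta_b over the masked genes.

    Collinear (|corr| > 0.995) or near-zero single deltas make the fit
    degenerate; such pairs are flagged and later excluded from ranking.
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    ab = np.asarray(delta_ab, dtype=float)
    if gene_mask is not None:
        mask = np.asarray(gene_mask)
        a, b, ab = a[mask], b[mask], ab[mask]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    similarity = _masked_corr(a, b)
    if na < ZERO_NORM_LIMIT or nb < ZERO_NORM_LIMIT or abs(similarity) > COLLINEARITY_LIMIT:
        return FitResult(np.nan, np.nan, np.nan, similarity, degenerate=True)
    x = np.column_stack([a, b])
    coef, *_ = np.linalg.lstsq(x, ab, rcond=None)
    fitted = x @ coef
    return FitResult(
        c_a=float(coef[0]),
        c_b=float(coef[1]),
        fit_corr=_masked_corr(fitted, ab),
        similarity=similarity,
    )


def de_union_mask(
    summary_a: ConditionSummary,
    summary_b: ConditionSummary,
    summary_ab: ConditionSummary,
    k: int = 20,
) -> np.ndarray:
    """Boolean mask over genes: union of the three top-k DE sets."""
    n = len(summary_ab.mean_delta)
    mask = np.zeros(n, dtype=bool)
    for s in (summary_a, summary_b, summary_ab):
        for g in s.top_k(k):
            mask[s.gene_column(g)] = True
    return mask


def _subtype_scores(fit: FitResult) -> dict:
    magnitude = float(np.hypot(fit.c_a, fit.c_b))
    abs_a, abs_b = abs(fit.c_a), abs(fit.c_b)
    equality = min(abs_a, abs_b) / max(abs_a, abs_b) if max(abs_a, abs_b) > 0 else 0.0
    dominance = abs(abs_a - abs_b) / magnitude if magnitude > 0 else 0.0
    return {
        "magnitude": magnitude,
        "equality": equality,
        "synergy": magnitude,
        "suppression": -magnitude,
        "neomorphism": -fit.fit_corr,
        "redundancy": fit.similarity - max(0.0, magnitude - np.sqrt(2.0)),
        "epistasis": dominance,
    }


@dataclass
class GIScoreTable:
    """All-pairs interaction scores; one row per unordered gene pair."""

    table: pd.DataFrame

    COLUMNS = [
        "gene_a",
        "gene_b",
        "c_a",
        "c_b",
        "fit_corr",
        "similarity",
        "magnitude",
        "equality",
        *GI_SUBTYPES,
        "uncertainty",
        "excluded",
    ]

    def scores(self, subtype: str, include_excluded: bool = False) -> dict:
        """Pair-key -> score map for one subtype (excluded pairs dropped)."""
        df = self.table if include_excluded else self.table[~self.table["excluded"]]
        keys = [canonical_condition({a, b}) for a, b in zip(df["gene_a"], df["gene_b"])]
        return dict(zip(keys, df[subtype].astype(float)))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def score_subtypes(fits: dict, uncertainties: dict | None = None) -> GIScoreTable:
    """Assemble a GIScoreTable from per-pair FitResults.

    ``fits`` maps an unordered pair (tuple or canonical key) to its
    :class:`FitResult`; degenerate fits are carried through flagged as
    excluded, with NaN scores.
    """
    rows = []
    for pair, fit in fits.items():
        key = canonical_condition(set(pair) if not isinstance(pair, str) else pair)
        a, b = sorted(key.split("+"))
        row = {"gene_a": a, "gene_b": b, "c_a": fit.c_a, "c_b": fit.c_b,
               "fit_corr": fit.fit_corr, "similarity": fit.similarity,
               "excluded": fit.degenerate}
        if fit.degenerate:
            row.update({c: np.nan for c in ("magnitude", "equality", *GI_SUBTYPES)})
        else:
            row.update(_subtype_scores(fit))
        row["uncertainty"] = (uncertainties or {}).get(key, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)[GIScoreTable.COLUMNS]
    return GIScoreTable(table=df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True))


def score_pairs(
    summaries: dict,
    pairs: list,
    k: int = 20,
    uncertainties: dict | None = None,
) -> GIScoreTable:
    """Fit and score a list of unordered pairs from condition summaries.

    ``summaries`` maps canonical condition keys (singles and doubles) to
    :class:`ConditionSummary` objects — measured or predicted; the same
    scoring pipeline serves both truth calling and model ranking.
    """
    fits = {}
    for pair in pairs:
        a, b = sorted(pair)
        key = canonical_condition({a, b})
        sa, sb, sab = summaries[a], summaries[b], summaries[key]
        mask = de_union_mask(sa, sb, sab, k=k)
        fits[key] = fit_combo_model(sa.mean_delta, sb.mean_delta, sab.mean_delta, mask)
    return score_subtypes(fits, uncertainties)


# -- ranking benchmarks --------------------------------------------------------

@dataclass
class RankingBenchmark:
    """Precision@k, top-k accuracy and PR curve for one subtype."""

    subtype: str
    precision_at_k: float
    top_k_accuracy: float
    k: int
    n_pairs: int
    n_truth_positive: int
    pr_curve: pd.DataFrame = field(repr=False, default=None)


def _ranked_keys(scores: dict) -> list:
    # sort by score descending, key ascending for determinism
    return [k for k, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]


def benchmark_ranking(
    predicted_scores: dict,
    truth_scores: dict,
    subtype: str = "",
    k: int = 10,
    truth_quantile: float = 0.9,
) -> RankingBenchmark:
    """Compare a predicted ranking against truth-derived labels.

    Truth positives are pairs whose truth score reaches its upper
    ``truth_quantile`` across all pairs (threshold config-exposed).
    precision@k is the truth-positive fraction of the top-k predictions;
    top-k accuracy is their overlap with truth's own top k.
    """
    common = sorted(set(predicted_scores) & set(truth_scores))
    if len(common) < k:
        raise ValueError(f"need at least k={k} pairs, have {len(common)}")
    pred = {p: predicted_scores[p] for p in common}
    true = {p: truth_scores[p] for p in common}
    threshold = np.quantile(list(true.values()), truth_quantile)
    positives = {p for p, v in true.items() if v >= threshold}
    pred_rank = _ranked_keys(pred)
    true_rank = _ranked_keys(true)
    top_pred = set(pred_rank[:k])
    prec = len(top_pred & positives) / k
    acc = len(top_pred & set(true_rank[:k])) / k
    # PR curve: sweep the predicted ranking prefix
    pr_rows = []
    hit = 0
    for i, p in enumerate(pred_rank, start=1):
        hit += p in positives
        pr_rows.append(
            {
                "rank": i,
                "precision": hit / i,
                "recall": hit / len(positives) if positives else 0.0,
            }
        )
    return RankingBenchmark(
        subtype=subtype,
        precision_at_k=prec,
        top_k_accuracy=acc,
        k=k,
        n_pairs=len(common),
        n_truth_positive=len(positives),
        pr_curve=pd.DataFrame(pr_rows),
    )


def random_ranking_precision(
    n_pairs: int,
    n_positive: int,
    k: int = 10,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple:
    """Monte-Carlo precision@k of a random ranking (the random model of
    the ranking benchmark); returns (mean, sd) over ``n_draws`` draws.

    The analytic expectation is n_positive / n_pairs.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_pairs)
    labels[:n_positive] = 1.0
    draws = np.empty(n_draws)
    for i in range(n_draws):
        draws[i] = rng.permutation(labels)[:k].mean()
    return float(draws.mean()), float(draws.std(ddof=1))


# -- all-pairs interaction map -------------------------------------------------

def gi_map(
    model: PerturbModel,
    gene_panel: list,
    ds: PerturbDataset,
    k: int = 20,
    batch_size: int = 256,
) -> GIScoreTable:
    """Predict and score every unordered pair of a gene panel.

    Enumerates all n·(n−1)/2 distinct pairs (a 102-gene panel gives
    5,151), predicts the n single and n·(n−1)/2 double conditions in
    batches, and scores all five subtypes. The map is symmetric by
    construction (conditions are unordered sets). Pairs whose genes are
    isolated in the perturbation graph are not dropped — their scalar
    uncertainty flags them as low-confidence.
    """
    panel = list(dict.fromkeys(gene_panel))
    pairs = list(itertools.combinations(panel, 2))
    conds = [frozenset({g}) for g in panel] + [frozenset(p) for p in pairs]
    ctrl_mean = ds.control_mean()
    summaries: dict = {}
    uncertainties: dict = {}
    from .data import rank_de_genes  # local import to avoid cycle at module load

    for start in range(0, len(conds), batch_size):
        chunk = conds[start : start + batch_size]
        z_hat, s = model.forward_batch(chunk)
        for pert_set, z_row, s_row in zip(chunk, z_hat.data, s.data):
            key = canonical_condition(pert_set)
            summaries[key] = ConditionSummary(
                condition_key=key,
                mean_expression=ctrl_mean + z_row,
                mean_delta=z_row.copy(),
                n_cells=0,
                top_de_genes=rank_de_genes(z_row, model.gene_names),
                gene_names=model.gene_names,
            )
            if len(pert_set) == 2:
                uncertainties[key] = model._scalar_uncertainty(z_row, s_row)
    return score_pairs(summaries, pairs, k=k, uncertainties=uncertainties)
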