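"""Download-free Perturb-seq-like simulator with known ground truth.

The generator emulates the data regime the predictor is built for: a
log-normalized expression matrix with a large unperturbed control
population, single-gene perturbation conditions, and two-gene conditions
whose effects are additive except for planted genetic interactions of
five subtypes.

Generative model
----------------
* A synthetic pathway ontology assigns each gene one or more pathway
  terms. Every pathway carries a latent effect direction in expression
  space; a perturbed gene's true effect vector is a convex mixture of
  its pathways' latent directions (weight ``neighbor_sharing``) and a
  private component. Genes annotated to the same pathways therefore
  have correlated perturbation effects — the inductive bias the
  pathway-similarity graph is meant to exploit — with correlation
  approximately equal to ``neighbor_sharing`` for genes sharing all
  their pathways.
* Two-gene condition effects are the sum of the single effects, except
  planted pairs:
    - synergy:      combo = 2.0 × (e_a + e_b)
    - suppression:  combo = 0.25 × (e_a + e_b)
    - neomorphism:  combo = 0.5 × (e_a + e_b) + novel direction
    - redundancy:   e_b ≈ e_a (near-duplicate singles),
                    combo = 0.55 × (e_a + e_b)  (sub-additive)
    - epistasis:    combo = e_a (gene a masks gene b)
* Cells are condition mean (baseline + effect) plus i.i.d. Gaussian
  noise on the log scale, clipped at zero; an optional negative-binomial
  counts layer exercises the raw-counts reader path.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .data import CTRL, PerturbDataset, canonical_condition
from .graphs import PathwayMembership

__all__ = ["SimConfig", "TruthTables", "simulate", "truth_metrics", "SUBTYPES"]

SUBTYPES = ("synergy", "suppression", "neomorphism", "redundancy", "epistasis")

# planted-pair transformations of the additive null
_SYNERGY_SCALE = 2.0
_SUPPRESSION_SCALE = 0.25
_NEOMORPH_ADDITIVE = 0.5
_NEOMORPH_NOVEL = 1.0  # novel-component norm relative to ||e_a + e_b||
_REDUNDANCY_SCALE = 0.55
_REDUNDANCY_TWIN_NOISE = 0.25  # relative sd of the near-duplicate single


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen (defaults are the
    desk-scale regime every recovery benchmark runs at)."""

    n_genes: int = 100
    n_pathways: int = 12
    pathways_per_gene: float = 1.0  # expected memberships per gene (>=1 realized)
    n_single: int = 40
    n_double: int = 30
    planted_per_subtype: int = 5
    cells_per_condition: int = 50
    n_control: int = 500
    effect_scale: float = 0.2  # sd of per-gene effect entries (log scale)
    neighbor_sharing: float = 0.9  # fraction of effect variance from pathway latents
    noise_sd: float = 0.2  # Gaussian noise on log expression
    nb_counts: bool = False  # also emit an NB raw-counts layer
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_pathways, self.n_single, self.cells_per_condition, self.n_control) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.neighbor_sharing <= 1.0:
            raise ValueError("neighbor_sharing must be in [0, 1]")
        if self.planted_per_subtype * len(SUBTYPES) > self.n_double:
            raise ValueError("planted pairs exceed the number of double conditions")


@dataclass
class TruthTables:
    """Ground truth of a simulated screen."""

    baseline: np.ndarray  # control mean on log scale (K,)
    single_effects: dict  # gene -> (K,) true effect vector
    double_effects: dict  # canonical "a+b" key -> (K,) true effect vector
    planted: dict  # subtype -> list of canonical pair keys
    additive_pairs: list  # pair keys left exactly additive
    gene_names: list

    def effect(self, condition: str) -> np.ndarray:
        key = canonical_condition(condition)
        if key == CTRL:
            return np.zeros_like(self.baseline)
        if key in self.double_effects:
            return self.double_effects[key]
        return self.single_effects[key]

    def to_json(self, path) -> None:
        obj = {
            "baseline": self.baseline.tolist(),
            "gene_names": self.gene_names,
            "single_effects": {g: v.tolist() for g, v in self.single_effects.items()},
            "double_effects": {k: v.tolist() for k, v in self.double_effects.items()},
            "planted": self.planted,
            "additive_pairs": self.additive_pairs,
        }
        Path(path).write_text(json.dumps(obj))


def _draw_membership(rng, cfg: SimConfig) -> PathwayMembership:
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    membership = {}
    extra_rate = max(cfg.pathways_per_gene - 1.0, 0.0)
    for g in genes:
        n_terms = 1 + rng.poisson(extra_rate)
        n_terms = min(n_terms, cfg.n_pathways)
        terms = rng.choice(cfg.n_pathways, size=n_terms, replace=False)
        membership[g] = frozenset(f"PW{t:03d}" for t in sorted(terms))
    return PathwayMembership(membership=membership)


def _single_effect(rng, cfg, gene, membership, latents) -> np.ndarray:
    terms = sorted(membership.terms(gene))
    shared = np.sum([latents[t] for t in terms], axis=0) / np.sqrt(len(terms))
    private = rng.normal(0.0, cfg.effect_scale, size=cfg.n_genes)
    s = cfg.neighbor_sharing
    return np.sqrt(s) * shared + np.sqrt(1.0 - s) * private


def _pick_planted_pairs(rng, cfg, singles, membership):
    """Planted pairs per subtype plus leftover additive pairs.

    Redundancy pairs get dedicated genes (their single effects are
    overwritten to near-duplicates); epistasis pairs prefer genes with
    no shared pathway so the masked gene's effect is clearly distinct.
    """
    n_plant = cfg.planted_per_subtype
    pool = list(singles)
    rng.shuffle(pool)
    # redundancy pairs are same-pathway paralogs with dedicated genes:
    # the twin's near-duplicate effect then stays consistent with its
    # pathway latent, which other planted pairs' genes must not share
    redundancy = []
    for _ in range(n_plant):
        pair = next(
            (
                (a, b)
                for i, a in enumerate(pool)
                for b in pool[i + 1 :]
                if membership.terms(a) & membership.terms(b)
            ),
            None,
        )
        if pair is None:  # no same-pathway candidates left
            pair = (pool[0], pool[1])
        pool.remove(pair[0])
        pool.remove(pair[1])
        redundancy.append(pair)
    used = set()

    def take_pair(prefer_disjoint_pathways: bool):
        candidates = [
            (a, b)
            for i, a in enumerate(pool)
            for b in pool[i + 1 :]
            if frozenset((a, b)) not in used
        ]
        if prefer_disjoint_pathways:
            disjoint = [
                (a, b) for a, b in candidates if not (membership.terms(a) & membership.terms(b))
            ]
            candidates = disjoint or candidates
        pair = candidates[rng.integers(len(candidates))]
        used.add(frozenset(pair))
        return pair

    planted = {"redundancy": redundancy}
    for subtype in ("synergy", "suppression", "neomorphism"):
        planted[subtype] = [take_pair(False) for _ in range(n_plant)]
    planted["epistasis"] = [take_pair(True) for _ in range(n_plant)]
    n_additive = cfg.n_double - n_plant * len(SUBTYPES)
    additive = [take_pair(False) for _ in range(n_additive)]
    return planted, additive


def simulate(config: SimConfig | None = None):
    """Draw a synthetic screen; returns (dataset, membership, truth)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    membership = _draw_membership(rng, cfg)
    genes = membership.genes()
    baseline = rng.uniform(1.5, 3.5, size=cfg.n_genes)
    latents = {
        f"PW{t:03d}": rng.normal(0.0, cfg.effect_scale, size=cfg.n_genes)
        for t in range(cfg.n_pathways)
    }
    singles = list(rng.choice(genes, size=cfg.n_single, replace=False))
    single_effects = {g: _single_effect(rng, cfg, g, membership, latents) for g in singles}

    planted, additive_pairs = _pick_planted_pairs(rng, cfg, singles, membership)
    # redundancy: overwrite the twin's single effect with a near-duplicate
    for a, b in planted["redundancy"]:
        twin_noise = rng.normal(
            0.0, _REDUNDANCY_TWIN_NOISE * cfg.effect_scale, size=cfg.n_genes
        )
        single_effects[b] = single_effects[a] + twin_noise

    double_effects = {}
    planted_keys = {s: [] for s in SUBTYPES}
    for subtype, pairs in planted.items():
        for a, b in pairs:
            e_add = single_effects[a] + single_effects[b]
            if subtype == "synergy":
                eff = _SYNERGY_SCALE * e_add
            elif subtype == "suppression":
                eff = _SUPPRESSION_SCALE * e_add
            elif subtype == "neomorphism":
                novel = rng.normal(0.0, 1.0, size=cfg.n_genes)
                novel *= _NEOMORPH_NOVEL * np.linalg.norm(e_add) / np.linalg.norm(novel)
                eff = _NEOMORPH_ADDITIVE * e_add + novel
            elif subtype == "redundancy":
                eff = _REDUNDANCY_SCALE * e_add
            else:  # epistasis: the name-sorted first gene masks the other
                eff = single_effects[min(a, b)].copy()
            key = canonical_condition({a, b})
            double_effects[key] = eff
            planted_keys[subtype].append(key)
    additive_keys = []
    for a, b in additive_pairs:
        key = canonical_condition({a, b})
        double_effects[key] = single_effects[a] + single_effects[b]
        additive_keys.append(key)

    truth = TruthTables(
        baseline=baseline,
        single_effects=single_effects,
        double_effects=double_effects,
        planted=planted_keys,
        additive_pairs=additive_keys,
        gene_names=genes,
    )

    # draw cells: condition mean + Gaussian log-scale noise
    rows, sets = [], []
    def emit(mean, pert_set, n):
        cells = np.broadcast_to(mean, (n, cfg.n_genes)).copy()
        if cfg.noise_sd > 0:
            cells += rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_genes))
        rows.append(np.clip(cells, 0.0, None))
        sets.extend([frozenset(pert_set)] * n)

    emit(baseline, (), cfg.n_control)
    for g in singles:
        emit(baseline + single_effects[g], {g}, cfg.cells_per_condition)
    for key, eff in double_effects.items():
        emit(baseline + eff, set(key.split("+")), cfg.cells_per_condition)
    ds = PerturbDataset(
        expression=np.vstack(rows), gene_names=genes, perturbation_sets=sets
    )
    if cfg.nb_counts:
        ds.counts = _nb_counts(rng, ds.expression, cfg.nb_dispersion)
    return ds, membership, truth


def _nb_counts(rng, logexpr: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts whose log-normalized means track logexpr."""
    mu = np.expm1(logexpr)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mu, 1e-9))
    return rng.negative_binomial(r, p).astype(np.int64)


def truth_metrics(truth: TruthTables, predictions: dict) -> pd.DataFrame:
    """Pearson correlation of predicted vs true effect, per condition.

    ``predictions`` maps condition key -> predicted delta vector.
    Zero-variance vectors correlate 0 by convention.
    """
    rows = []
    for key, pred in predictions.items():
        true = truth.effect(key)
        pred = np.asarray(pred, dtype=float)
        if np.std(pred) < 1e-12 or np.std(true) < 1e-12:
            r = 0.0
        else:
            r = float(np.corrcoef(pred, true)[0, 1])
        rows.append({"condition": key, "pearson_delta": r})
    return pd.DataFrame(rows)
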