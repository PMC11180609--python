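"""Perturbation dataset container, condition summaries and train/test splits.

The central object is :class:`PerturbDataset`: an N-cell × K-gene
log-normalized expression matrix where every cell carries a *perturbation
set* — the set of gene targets perturbed in that cell (empty for
unperturbed controls). Conditions are named canonically: ``"ctrl"`` for
controls and the sorted ``"+"``-joined target names otherwise, so that
``"A+B"`` and ``"B+A"`` are the same condition and the ``"GENE+ctrl"``
dialect used by public Perturb-seq depositions parses to ``"GENE"``.

Summaries (:func:`summarize_condition`) report per-condition mean
expression and the *delta* — mean expression minus the control mean —
together with genes ranked by absolute delta (the most differentially
expressed genes). Splits (:func:`make_split`) hold out whole conditions
and label two-gene test conditions by how many constituent genes were
seen perturbed during training (0, 1 or 2 of 2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PerturbDataset",
    "ConditionSummary",
    "SplitPlan",
    "canonical_condition",
    "load_dataset",
    "summarize_condition",
    "make_split",
]

CTRL = "ctrl"


def canonical_condition(condition: str | set | frozenset | list | tuple) -> str:
    """Canonical condition key: ``"ctrl"`` or sorted ``"+"``-joined targets.

    Accepts either a perturbation set or a condition string in the
    public dialect (``"ctrl"``, ``"GENE+ctrl"``, ``"GENE1+GENE2"``).
    Idempotent on its own output.
    """
    if isinstance(condition, str):
        tokens = [t for t in condition.split("+") if t and t != CTRL]
    else:
        tokens = [t for t in condition if t != CTRL]
    if not tokens:
        return CTRL
    return "+".join(sorted(set(tokens)))


def condition_targets(key: str) -> frozenset:
    """Perturbation set of a canonical condition key."""
    return frozenset() if key == CTRL else frozenset(key.split("+"))


@dataclass
class PerturbDataset:
    """Cells × genes expression with per-cell perturbation sets.

    Attributes
    ----------
    expression : (N, K) float array, log-normalized, non-negative.
    gene_names : K gene identifiers (matrix columns).
    perturbation_sets : per cell, frozenset of perturbed gene targets.
    condition_key : per cell, canonical condition string.
    unmeasured_targets : perturbation targets with no expression column
        (kept in perturbation sets, excluded from expression metrics).
    """

    expression: np.ndarray
    gene_names: list
    perturbation_sets: list
    condition_key: np.ndarray = None
    unmeasured_targets: set = field(default_factory=set)
    warnings_: list = field(default_factory=list)

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        n, k = self.expression.shape
        if len(self.perturbation_sets) != n:
            raise ValueError("perturbation_sets length must equal cell count")
        if len(self.gene_names) != k:
            raise ValueError("gene_names length must equal gene count")
        self.perturbation_sets = [frozenset(s) for s in self.perturbation_sets]
        keys = np.array([canonical_condition(s) for s in self.perturbation_sets])
        if self.condition_key is None:
            self.condition_key = keys
        else:
            self.condition_key = np.asarray(self.condition_key)
            if not np.array_equal(self.condition_key, keys):
                raise ValueError("condition_key inconsistent with perturbation_sets")
        measured = set(self.gene_names)
        seen_unmeasured = {t for s in self.perturbation_sets for t in s} - measured
        self.unmeasured_targets = set(self.unmeasured_targets) | seen_unmeasured
        if self.n_control == 0:
            msg = "dataset has no control cells"
            self.warnings_.append(msg)
            warnings.warn(msg, stacklevel=2)

    # -- basic accessors ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_control(self) -> int:
        return int(np.sum(self.condition_key == CTRL))

    @property
    def conditions(self) -> list:
        """Sorted unique condition keys."""
        return sorted(set(self.condition_key))

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not measured") from None

    def cells_of(self, condition: str) -> np.ndarray:
        """Row indices of a condition's cells."""
        key = canonical_condition(condition)
        idx = np.flatnonzero(self.condition_key == key)
        if idx.size == 0:
            raise KeyError(f"unknown condition {key!r}")
        return idx

    def control_mean(self) -> np.ndarray:
        if self.n_control == 0:
            raise ValueError("control mean requested but no control cells exist")
        return self.expression[self.condition_key == CTRL].mean(axis=0)

    def subset(self, cell_idx: np.ndarray) -> "PerturbDataset":
        cell_idx = np.asarray(cell_idx)
        return PerturbDataset(
            expression=self.expression[cell_idx],
            gene_names=self.gene_names,
            perturbation_sets=[self.perturbation_sets[i] for i in cell_idx],
            unmeasured_targets=set(self.unmeasured_targets),
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.expression.astype(np.float32),
            obs=pd.DataFrame(
                {"condition": pd.Categorical(self.condition_key)},
                index=[f"cell_{i}" for i in range(self.n_cells)],
            ),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        return adata


# -- loading ------------------------------------------------------------------

def _log_normalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-``target_sum`` per cell, then log1p."""
    counts = np.asarray(counts, dtype=np.float64)
    libsize = counts.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    return np.log1p(counts / libsize * target_sum)


def _is_integer_valued(x: np.ndarray) -> bool:
    return bool(np.all(x >= 0) and np.allclose(x, np.round(x)))


def load_dataset(path, perturbation_field: str = "condition") -> PerturbDataset:
    """Read an H5AD file or an MTX directory into a :class:`PerturbDataset`.

    ``perturbation_field`` names the per-cell annotation column holding
    condition strings (``"ctrl"`` / ``"GENE+ctrl"`` / ``"GENE1+GENE2"``).
    Integer-valued matrices are treated as raw counts and log-normalized
    (counts per 10k, log1p); float matrices are taken as already
    normalized.
    """
    path = Path(path)
    if path.is_dir():
        adata = _read_mtx_dir(path, perturbation_field)
    else:
        adata = ad.read_h5ad(path)
    if adata.X is None:
        raise ValueError(f"{path}: no expression matrix found")
    if perturbation_field not in adata.obs.columns:
        raise KeyError(
            f"perturbation field {perturbation_field!r} not found; "
            f"available obs fields: {list(adata.obs.columns)}"
        )
    x = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    x = x.astype(np.float64)
    if _is_integer_valued(x):
        x = _log_normalize(x)
    sets = [
        condition_targets(canonical_condition(str(c)))
        for c in adata.obs[perturbation_field]
    ]
    return PerturbDataset(
        expression=x,
        gene_names=[str(g) for g in adata.var_names],
        perturbation_sets=sets,
    )


def _read_mtx_dir(path: Path, perturbation_field: str) -> ad.AnnData:
    """MTX triplet directory: matrix.mtx + genes.tsv + barcodes.tsv.

    The matrix is genes × cells (10x convention); barcodes.tsv carries
    the condition string in its second column when present.
    """
    import scipy.io as sio

    mtx = next(iter(sorted(path.glob("*.mtx"))), None)
    if mtx is None:
        raise ValueError(f"{path}: no .mtx matrix found")
    x = sio.mmread(mtx)
    x = x.toarray() if sp.issparse(x) else np.asarray(x)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    x = x.T  # to cells × genes
    if x.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"{path}: matrix shape {x.shape} does not match "
            f"{len(barcodes)} barcodes × {len(genes)} genes"
        )
    obs = pd.DataFrame(index=barcodes[0].astype(str))
    if barcodes.shape[1] > 1:
        obs[perturbation_field] = barcodes[1].astype(str).values
    var = pd.DataFrame(index=genes[0].astype(str))
    return ad.AnnData(X=x.astype(np.float64), obs=obs, var=var)


# -- condition summaries -------------------------------------------------------

@dataclass
class ConditionSummary:
    """Per-condition mean expression, delta over control and DE ranking."""

    condition_key: str
    mean_expression: np.ndarray
    mean_delta: np.ndarray
    n_cells: int
    top_de_genes: list  # all genes ranked by |mean_delta| (desc), ties by index
    gene_names: list = None  # matrix column order; None = unknown

    def top_k(self, k: int = 20) -> list:
        return self.top_de_genes[:k]

    def gene_column(self, gene) -> int:
        if self.gene_names is not None:
            return self.gene_names.index(gene)
        # top_de_genes is the rank_de_genes permutation; invert it
        order = np.lexsort((np.arange(len(self.mean_delta)), -np.abs(self.mean_delta)))
        return int(order[self.top_de_genes.index(gene)])


def rank_de_genes(mean_delta: np.ndarray, gene_names: list) -> list:
    """Genes ranked by |delta| descending; ties broken by gene index."""
    order = np.lexsort((np.arange(len(gene_names)), -np.abs(mean_delta)))
    return [gene_names[i] for i in order]


def summarize_condition(ds: PerturbDataset, condition_key: str) -> ConditionSummary:
    """Mean expression and differential expression over control for one condition."""
    key = canonical_condition(condition_key)
    cells = ds.cells_of(key)
    mean = ds.expression[cells].mean(axis=0)
    if key == CTRL:
        delta = np.zeros_like(mean)
    else:
        delta = mean - ds.control_mean()
    return ConditionSummary(
        condition_key=key,
        mean_expression=mean,
        mean_delta=delta,
        n_cells=int(cells.size),
        top_de_genes=rank_de_genes(delta, ds.gene_names),
        gene_names=list(ds.gene_names),
    )


def summary_table(summaries) -> pd.DataFrame:
    """Long-format TSV-ready table of condition summaries."""
    rows = []
    for s in summaries:
        for i, g in enumerate(s.top_de_genes[:20]):
            rows.append(
                {
                    "condition": s.condition_key,
                    "n_cells": s.n_cells,
                    "de_rank": i + 1,
                    "gene": g,
                }
            )
    return pd.DataFrame(rows)


# -- train/test splits ---------------------------------------------------------

SPLIT_CLASSES = ("single_unseen", "combo_seen0", "combo_seen1", "combo_seen2")


@dataclass
class SplitPlan:
    """Condition-level train/validation/test split with generalization classes."""

    train: list
    val: list
    test: list
    test_class: dict  # condition -> class

    def cells(self, ds: PerturbDataset, part: str) -> np.ndarray:
        keys = {"train": self.train, "val": self.val, "test": self.test}[part]
        mask = np.isin(ds.condition_key, list(keys))
        return np.flatnonzero(mask)

    def train_targets(self) -> set:
        return {t for c in self.train for t in condition_targets(c)}

    def to_json(self, path=None) -> str:
        obj = {
            "train": self.train,
            "val": self.val,
            "test": [{"condition": c, "class": self.test_class[c]} for c in self.test],
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SplitPlan":
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else source)
        test = [t["condition"] for t in obj["test"]]
        return cls(
            train=list(obj["train"]),
            val=list(obj["val"]),
            test=test,
            test_class={t["condition"]: t["class"] for t in obj["test"]},
        )


def _classify(condition: str, train_targets: set) -> str:
    targets = condition_targets(condition)
    if len(targets) == 1:
        return "single_unseen"
    seen = sum(t in train_targets for t in targets)
    return f"combo_seen{seen}"


def make_split(
    ds: PerturbDataset,
    mode: str = "single",
    fractions: tuple = (0.25, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Hold out whole perturbation conditions for testing.

    Parameters
    ----------
    mode : ``"single"`` holds out single-gene conditions only;
        ``"combo"`` additionally holds out two-gene conditions and, by
        holding out some singles too, produces 0/1/2-of-2-unseen test
        classes.
    fractions : (test_fraction, val_fraction) of conditions; must sum
        to at most 1.
    seed : split is a pure function of the dataset and this seed.
    """
    test_frac, val_frac = fractions
    if test_frac + val_frac > 1 or test_frac < 0 or val_frac < 0:
        raise ValueError(f"invalid fractions {fractions}: must be >=0 and sum to <=1")
    singles = sorted(c for c in ds.conditions if len(condition_targets(c)) == 1)
    combos = sorted(c for c in ds.conditions if len(condition_targets(c)) >= 2)
    if mode not in ("single", "combo"):
        raise ValueError(f"unknown split mode {mode!r}")
    if mode == "combo" and not combos:
        raise ValueError("combo split requires at least one multi-gene condition")

    rng = np.random.default_rng(seed)

    def partition(conds):
        conds = list(conds)
        rng.shuffle(conds)
        n_test = int(round(test_frac * len(conds)))
        n_val = int(round(val_frac * len(conds)))
        return conds[:n_test], conds[n_test : n_test + n_val], conds[n_test + n_val :]

    te_s, va_s, tr_s = partition(singles)
    if mode == "single":
        train = tr_s + combos
        val, test = va_s, te_s
    else:
        te_c, va_c, tr_c = partition(combos)
        train = tr_s + tr_c
        val = va_s + va_c
        test = te_s + te_c
    if CTRL in ds.conditions:
        train = [CTRL] + [c for c in train if c != CTRL]
    # a held-out single's gene must never appear as a target in training,
    # so combos touching held-out single targets are excluded from train
    held_single_targets = {
        t
        for c in test + val
        if len(condition_targets(c)) == 1
        for t in condition_targets(c)
    }
    train = [
        c
        for c in train
        if len(condition_targets(c)) <= 1
        or not (condition_targets(c) & held_single_targets)
    ]
    train_targets = {t for c in train for t in condition_targets(c)}
    test_class = {c: _classify(c, train_targets) for c in test}
    return SplitPlan(train=sorted(train), val=sorted(val), test=sorted(test), test_class=test_class)
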