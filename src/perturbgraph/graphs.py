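"""Knowledge-graph construction: coexpression and pathway-similarity graphs.

Two graphs condition the perturbation model:

* a **gene coexpression graph** — for each gene, directed edges from its
  top-``H_gene`` most Pearson-correlated genes (computed on training
  cells only) whose correlation exceeds a threshold ``delta``;
* a **perturbation similarity graph** — for each gene, edges from the
  top-``H_pert`` genes by Jaccard index of shared pathway annotations
  (a GO-like bipartite gene–term relation).

Edges are stored directed as ``u -> v`` meaning "v is among u's top-H
neighbors"; message passing later aggregates *into* u from those
neighbors. Top-H selection is a stable sort by (−similarity, gene
index), so graph construction is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PerturbDataset

__all__ = [
    "GeneGraph",
    "PathwayMembership",
    "build_coexpression_graph",
    "jaccard_similarity",
    "build_perturbation_graph",
    "shuffle_edges",
]


@dataclass
class GeneGraph:
    """Weighted directed top-H neighbor graph over genes or perturbations."""

    node_ids: list
    edges: list  # (source, target, weight) with source's neighbor = target
    kind: str  # "coexpression" | "perturbation_similarity"

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        index = {g: i for i, g in enumerate(self.node_ids)}
        for s, t, w in self.edges:
            if s == t:
                raise ValueError(f"self-loop on {s!r}")
            if s not in index or t not in index:
                raise ValueError(f"edge ({s},{t}) references unknown node")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({s},{t})")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def out_degree(self, node) -> int:
        return sum(1 for s, _, _ in self.edges if s == node)

    def neighbors(self, node) -> list:
        """Targets of ``node``'s outgoing edges (its selected top-H set)."""
        return [t for s, t, _ in self.edges if s == node]

    def adjacency(self, normalize: bool = True, use_weights: bool = True) -> np.ndarray:
        """Dense aggregation matrix A with A[u, v] the weight of neighbor v
        in u's aggregation; rows normalized to sum to 1 over neighbors."""
        index = {g: i for i, g in enumerate(self.node_ids)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for s, t, w in self.edges:
            a[index[s], index[t]] = w if use_weights else 1.0
        if normalize:
            rowsum = np.abs(a).sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            a = a / rowsum
        return a

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, node_ids=None, kind: str = "coexpression") -> "GeneGraph":
        df = pd.read_csv(path, sep="\t")
        edges = [(str(r.source), str(r.target), float(r.weight)) for r in df.itertuples()]
        if node_ids is None:
            node_ids = sorted({n for e in edges for n in e[:2]})
        return cls(node_ids=node_ids, edges=edges, kind=kind)


@dataclass
class PathwayMembership:
    """Bipartite gene -> set-of-pathway-terms relation."""

    membership: dict = field(default_factory=dict)

    def terms(self, gene) -> frozenset:
        return frozenset(self.membership.get(gene, ()))

    def genes(self) -> list:
        return sorted(self.membership)

    def to_tsv(self, path) -> None:
        rows = [(g, t) for g in sorted(self.membership) for t in sorted(self.membership[g])]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PathwayMembership":
        df = pd.read_csv(path, sep="\t")
        gene_col, term_col = df.columns[:2]
        membership: dict = {}
        for g, t in zip(df[gene_col].astype(str), df[term_col].astype(str)):
            membership.setdefault(g, set()).add(t)
        return cls(membership={g: frozenset(s) for g, s in membership.items()})


def _top_h_edges(node_ids, sim: np.ndarray, h: int, min_exclusive: float) -> list:
    """Per-row top-``h`` neighbors with similarity strictly above
    ``min_exclusive``; ties broken by (−similarity, index) stable order."""
    k = len(node_ids)
    edges = []
    for u in range(k):
        row = sim[u].copy()
        row[u] = -np.inf
        order = np.lexsort((np.arange(k), -row))
        for v in order[:h]:
            if row[v] > min_exclusive:
                edges.append((node_ids[u], node_ids[v], float(row[v])))
    return edges


def build_coexpression_graph(
    ds: PerturbDataset,
    h_gene: int = 20,
    delta: float = 0.1,
    train_cells: np.ndarray | None = None,
) -> GeneGraph:
    """Top-``h_gene`` Pearson-correlation neighbors per gene, above ``delta``.

    Correlations are computed over ``train_cells`` only (all cells when
    None), so the graph never sees held-out conditions. A gene with zero
    variance has all its correlations defined as 0.
    """
    if h_gene < 1:
        raise ValueError("h_gene must be >= 1")
    x = ds.expression if train_cells is None else ds.expression[np.asarray(train_cells)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells to compute correlations")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(x, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)  # zero-variance genes correlate 0
    np.clip(rho, -1.0, 1.0, out=rho)
    edges = _top_h_edges(ds.gene_names, rho, h_gene, min_exclusive=delta)
    return GeneGraph(node_ids=ds.gene_names, edges=edges, kind="coexpression")


def jaccard_similarity(membership: PathwayMembership, u, v) -> float:
    """|N_u ∩ N_v| / |N_u ∪ N_v|; 0 when both annotation sets are empty."""
    nu, nv = membership.terms(u), membership.terms(v)
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def build_perturbation_graph(
    membership: PathwayMembership,
    genes: list,
    h_pert: int = 20,
) -> GeneGraph:
    """Top-``h_pert`` Jaccard-similarity neighbors per gene.

    Zero-similarity edges are dropped, so genes with no shared pathway
    annotation (or none at all) end up isolated.
    """
    if h_pert < 1:
        raise ValueError("h_pert must be >= 1")
    genes = list(genes)
    k = len(genes)
    sim = np.zeros((k, k))
    term_sets = [membership.terms(g) for g in genes]
    for i in range(k):
        for j in range(i + 1, k):
            union = term_sets[i] | term_sets[j]
            if union:
                sim[i, j] = sim[j, i] = len(term_sets[i] & term_sets[j]) / len(union)
    edges = _top_h_edges(genes, sim, h_pert, min_exclusive=0.0)
    return GeneGraph(node_ids=genes, edges=edges, kind="perturbation_similarity")


def shuffle_edges(graph: GeneGraph, seed: int = 0) -> GeneGraph:
    """Degree-preserving edge randomization (ablation control).

    Each edge keeps its source and weight but is rewired to a random
    target, destroying the similarity structure while preserving
    out-degrees and the weight distribution.
    """
    rng = np.random.default_rng(seed)
    nodes = graph.node_ids
    edges = []
    for s, _, w in graph.edges:
        choices = [n for n in nodes if n != s]
        edges.append((s, choices[rng.integers(len(choices))], w))
    return GeneGraph(node_ids=list(nodes), edges=edges, kind=graph.kind)
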