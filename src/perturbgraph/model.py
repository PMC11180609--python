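"""The perturbation-prediction network.

Architecture, in the order a prediction flows:

1. every measured gene gets a learnable *gene embedding*, every
   perturbable target a learnable *perturbation embedding* (two distinct
   vectors per gene);
2. a graph-convolution layer refines gene embeddings over the
   coexpression graph and perturbation embeddings over the
   pathway-similarity graph, so information propagates from graph
   neighbors — this is what lets a never-perturbed gene inherit a
   meaningful perturbation representation from its pathway neighbors;
3. the perturbation embeddings of the applied target set are summed
   (a permutation-invariant compositional operator that extends to any
   set size) and passed through an MLP;
4. each gene's refined embedding plus the composed perturbation vector
   is passed through a shared post-perturbation MLP, then a per-gene
   linear head reads out a scalar effect z_u;
5. a cross-gene MLP summarizes the whole effect vector z into one
   cell-level embedding which, concatenated with z_u, feeds a second
   per-gene head producing the final effect ẑ_u; the prediction is
   ĝ = ẑ + g_ctrl for a sampled unperturbed control cell;
6. a per-gene uncertainty head reads a log-variance s_u from the same
   post-perturbation embedding.

Control conditions bypass the network: the model predicts perturbation
effects only, so the prediction for "ctrl" is the control profile itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as adf
from .autodiff import Tensor
from .data import CTRL, ConditionSummary, PerturbDataset, canonical_condition, condition_targets, rank_de_genes
from .graphs import GeneGraph

__all__ = ["ModelConfig", "PerturbModel", "PredictionResult"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    d : embedding dimension for genes, perturbations and hidden layers.
    n_gnn_layers : graph-convolution layers per graph (1 = one-hop).
    use_edge_weights : weight neighbor aggregation by edge similarity.
    uncertainty_aggregation : how the scalar uncertainty summarizes the
        per-gene log-variances — "top_de" averages over the predicted
        profile's 20 most differentially expressed genes (mirroring the
        autofocus emphasis), "all" over every gene.
    """

    d: int = 64
    n_gnn_layers: int = 1
    use_edge_weights: bool = True
    uncertainty_aggregation: str = "top_de"
    n_top_de: int = 20
    embedding_init_scale: float = 0.02
    seed: int = 0


@dataclass
class PredictionResult:
    """Predicted outcome of one perturbation condition."""

    condition_key: str
    g_hat: np.ndarray  # predicted postperturbation expression (K,)
    z_hat: np.ndarray  # predicted perturbation effect (K,)
    s: np.ndarray  # per-gene log variance (K,)
    uncertainty: float


def _gene_list_hash(names) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


class PerturbModel:
    """All learnable parameters plus the fixed graph aggregation matrices."""

    def __init__(
        self,
        gene_names: list,
        g_gene: GeneGraph,
        g_pert: GeneGraph,
        pert_names: list | None = None,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.gene_names = list(gene_names)
        # perturbation targets: measured genes plus any extra (unmeasured) ids
        self.pert_names = list(pert_names) if pert_names is not None else list(gene_names)
        self.gene_index = {g: i for i, g in enumerate(self.gene_names)}
        self.pert_index = {g: i for i, g in enumerate(self.pert_names)}
        if not set(g_gene.node_ids) <= set(self.gene_names):
            raise ValueError("coexpression graph has nodes outside the gene list")
        if not set(g_pert.node_ids) <= set(self.pert_names):
            raise ValueError("perturbation graph has nodes outside the target list")
        self.a_gene = self._embed_adjacency(g_gene, self.gene_index, len(self.gene_names))
        self.a_pert = self._embed_adjacency(g_pert, self.pert_index, len(self.pert_names))
        self.graph_hash = _gene_list_hash(
            [f"{s}\t{t}\t{w:.6g}" for s, t, w in sorted(g_gene.edges) + sorted(g_pert.edges)]
        )
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters -----------------------------------------------------------
    def _embed_adjacency(self, graph: GeneGraph, index: dict, n: int) -> np.ndarray:
        a = np.zeros((n, n))
        sub = graph.adjacency(normalize=True, use_weights=self.config.use_edge_weights)
        ids = [index[g] for g in graph.node_ids]
        a[np.ix_(ids, ids)] = sub
        return a

    def _param(self, name: str, shape, scale: float) -> Tensor:
        t = Tensor(self._rng.normal(0.0, scale, size=shape), requires_grad=True)
        self.params[name] = t
        return t

    def _init_params(self):
        cfg = self.config
        d = cfg.d
        k, p = len(self.gene_names), len(self.pert_names)
        self._rng = np.random.default_rng(cfg.seed)
        he = np.sqrt(2.0 / d)
        self._param("x_gene", (k, d), cfg.embedding_init_scale)
        self._param("x_pert", (p, d), cfg.embedding_init_scale)
        for graph in ("gene", "pert"):
            for layer in range(cfg.n_gnn_layers):
                self._param(f"gnn_{graph}_self_{layer}", (d, d), he)
                self._param(f"gnn_{graph}_nbr_{layer}", (d, d), he)
                self._param(f"gnn_{graph}_bias_{layer}", (d,), 0.0)
        for mlp, d_in in (("compose", d), ("postpert", d), ("crossgene", k)):
            self._param(f"mlp_{mlp}_w1", (d_in, d), np.sqrt(2.0 / d_in))
            self._param(f"mlp_{mlp}_b1", (d,), 0.0)
            self._param(f"mlp_{mlp}_w2", (d, d), he)
            self._param(f"mlp_{mlp}_b2", (d,), 0.0)
        self._param("w_head", (k, d), 0.01)
        self._param("b_head", (k,), 0.0)
        self._param("w_cg", (k, d + 1), 0.01)
        self._param("b_cg", (k,), 0.0)
        self._param("w_unc", (k, d), 0.01)
        self._param("b_unc", (k,), 0.0)

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # -- building blocks ------------------------------------------------------
    def _gnn(self, x: Tensor, a: np.ndarray, graph: str) -> Tensor:
        h = x
        for layer in range(self.config.n_gnn_layers):
            w_self = self.params[f"gnn_{graph}_self_{layer}"]
            w_nbr = self.params[f"gnn_{graph}_nbr_{layer}"]
            b = self.params[f"gnn_{graph}_bias_{layer}"]
            h = adf.relu(h @ w_self + Tensor(a) @ (h @ w_nbr) + b)
        return h

    def _mlp(self, x: Tensor, name: str) -> Tensor:
        h = adf.relu(x @ self.params[f"mlp_{name}_w1"] + self.params[f"mlp_{name}_b1"])
        return h @ self.params[f"mlp_{name}_w2"] + self.params[f"mlp_{name}_b2"]

    def encode_genes(self) -> Tensor:
        """Refined gene embeddings h^gene (K × d) over the coexpression graph."""
        return self._gnn(self.params["x_gene"], self.a_gene, "gene")

    def encode_perturbations(self, embedding_mask: np.ndarray | None = None) -> Tensor:
        """Refined perturbation embeddings h^pert (P × d) over the pathway graph.

        ``embedding_mask`` (P,) zeroes selected raw embeddings before
        message passing; training uses it as node-embedding dropout so
        the network also learns the regime an unseen perturbation faces
        (no informative self-embedding, graph context only).
        """
        x = self.params["x_pert"]
        if embedding_mask is not None:
            x = x * Tensor(np.asarray(embedding_mask, dtype=float)[:, None])
        return self._gnn(x, self.a_pert, "pert")

    def compose_perturbations(self, pert_set, h_pert: Tensor) -> Tensor:
        """Sum the set's perturbation embeddings, then the compose MLP.

        Permutation-invariant by construction; the empty set gives a
        zero pre-MLP sum (callers route control conditions around the
        network entirely).
        """
        idx = self._pert_ids(pert_set)
        if idx.size:
            pre = h_pert.gather_rows(idx).sum(axis=0, keepdims=True)
        else:
            pre = Tensor(np.zeros((1, self.config.d)))
        return self._mlp(pre, "compose").reshape(self.config.d)

    def _pert_ids(self, pert_set) -> np.ndarray:
        ids = []
        for g in sorted(pert_set):
            if g not in self.pert_index:
                raise KeyError(f"perturbation target {g!r} has no perturbation embedding")
            ids.append(self.pert_index[g])
        return np.asarray(ids, dtype=np.intp)

    # -- forward --------------------------------------------------------------
    def forward_batch(self, pert_sets: list, embedding_mask: np.ndarray | None = None) -> tuple:
        """Predicted effect ẑ and log-variance s for a batch of conditions.

        Returns Tensors of shape (T, K); every set must be non-empty
        (controls bypass the network). ``embedding_mask`` is forwarded
        to :meth:`encode_perturbations` (training-time node dropout).
        """
        if any(len(s) == 0 for s in pert_sets):
            raise ValueError("forward_batch requires non-empty perturbation sets")
        t_n = len(pert_sets)
        k, d = len(self.gene_names), self.config.d
        h_gene = self.encode_genes()
        h_pert = self.encode_perturbations(embedding_mask)
        member = np.zeros((t_n, len(self.pert_names)))
        for i, s in enumerate(pert_sets):
            member[i, self._pert_ids(s)] = 1.0
        h_p = self._mlp(Tensor(member) @ h_pert, "compose")  # (T, d)
        base = h_gene.reshape(1, k, d) + h_p.reshape(t_n, 1, d)
        h_pp = self._mlp(base.reshape(t_n * k, d), "postpert").reshape(t_n, k, d)
        w_head = self.params["w_head"].reshape(1, k, d)
        z = (h_pp * w_head).sum(axis=2) + self.params["b_head"]  # (T, K)
        h_cg = self._mlp(z, "crossgene")  # (T, d)
        w_cg = self.params["w_cg"]
        z_hat = z * w_cg[:, 0] + h_cg @ w_cg[:, 1:].transpose() + self.params["b_cg"]
        s = (h_pp * self.params["w_unc"].reshape(1, k, d)).sum(axis=2) + self.params["b_unc"]
        return z_hat, s

    def _scalar_uncertainty(self, z_hat: np.ndarray, s: np.ndarray) -> float:
        if self.config.uncertainty_aggregation == "all":
            return float(s.mean())
        order = np.lexsort((np.arange(z_hat.size), -np.abs(z_hat)))
        return float(s[order[: self.config.n_top_de]].mean())

    def predict(self, pert_set, g_ctrl: np.ndarray) -> PredictionResult:
        """Full prediction for one perturbation set applied to one control cell."""
        g_ctrl = np.asarray(g_ctrl, dtype=np.float64)
        if g_ctrl.shape != (len(self.gene_names),):
            raise ValueError("g_ctrl must be a length-K expression vector")
        pert_set = frozenset(pert_set)
        if not pert_set:
            zeros = np.zeros_like(g_ctrl)
            return PredictionResult(CTRL, g_ctrl.copy(), zeros, zeros.copy(), 0.0)
        z_hat_t, s_t = self.forward_batch([pert_set])
        z_hat = z_hat_t.data[0]
        s = s_t.data[0]
        return PredictionResult(
            condition_key=canonical_condition(pert_set),
            g_hat=z_hat + g_ctrl,
            z_hat=z_hat,
            s=s,
            uncertainty=self._scalar_uncertainty(z_hat, s),
        )

    def predict_condition_mean(
        self,
        pert_set,
        ds: PerturbDataset,
        n_ctrl: int | None = None,
        seed: int = 0,
    ) -> ConditionSummary:
        """Mean predicted profile over sampled unperturbed control cells.

        With ``n_ctrl=None`` every control cell is used, so the mean
        prediction is exactly ẑ plus the control mean and the summary
        delta is ẑ itself.
        """
        if isinstance(pert_set, str):
            pert_set = condition_targets(canonical_condition(pert_set))
        ctrl_cells = ds.cells_of(CTRL)
        if n_ctrl is not None and n_ctrl < ctrl_cells.size:
            rng = np.random.default_rng(seed)
            ctrl_cells = rng.choice(ctrl_cells, size=n_ctrl, replace=False)
        ctrl_mean_sampled = ds.expression[ctrl_cells].mean(axis=0)
        res = self.predict(pert_set, ctrl_mean_sampled)
        delta = res.g_hat - ds.control_mean()
        return ConditionSummary(
            condition_key=res.condition_key,
            mean_expression=res.g_hat,
            mean_delta=delta,
            n_cells=int(ctrl_cells.size),
            top_de_genes=rank_de_genes(delta, self.gene_names),
            gene_names=list(self.gene_names),
        )

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write parameters (.npz) plus a JSON sidecar describing the model."""
        path = Path(path)
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__a_gene__"] = self.a_gene
        arrays["__a_pert__"] = self.a_pert
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "config": asdict(self.config),
            "gene_names": self.gene_names,
            "pert_names": self.pert_names,
            "gene_hash": _gene_list_hash(self.gene_names),
            "graph_hash": self.graph_hash,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PerturbModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if _gene_list_hash(sidecar["gene_names"]) != sidecar["gene_hash"]:
            raise ValueError("checkpoint gene list does not match its recorded hash")
        model = cls.__new__(cls)
        model.config = ModelConfig(**sidecar["config"])
        model.gene_names = sidecar["gene_names"]
        model.pert_names = sidecar["pert_names"]
        model.gene_index = {g: i for i, g in enumerate(model.gene_names)}
        model.pert_index = {g: i for i, g in enumerate(model.pert_names)}
        model.graph_hash = sidecar["graph_hash"]
        with np.load(path.with_suffix(".npz")) as npz:
            model.a_gene = npz["__a_gene__"]
            model.a_pert = npz["__a_pert__"]
            model.params = {
                k: Tensor(npz[k], requires_grad=True)
                for k in npz.files
                if not k.startswith("__")
            }
        return model
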