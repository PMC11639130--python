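"""Atom-level molecule encoding.

A molecular graph is encoded by K stacked message-passing layers over the
atom graph followed by sum pooling of the final atom states, giving the
atom-level molecule representation h^A. Four aggregator families are
provided: symmetric-normalized graph convolution (gcn), single-head
learned attention (gat), self/mean-neighbor concatenation (sage), and a
k-hop polynomial filter (tag).

Molecules are encoded in batches: atom graphs are stacked block-diagonally
so one sparse multiply propagates messages in every molecule at once, and
a molecule-membership matrix performs the sum pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .autodiff import Parameter, Tensor, sparse_mm
from .chemio import Molecule

AGGREGATORS = ("gcn", "gat", "sage", "tag")


@dataclass
class EncoderConfig:
    aggregator: str = "gcn"
    num_layers: int = 2
    hidden_dim: int = 256
    input_dim: int = 0  # F0; set when parameters are created
    tag_hops: int = 2
    leaky_slope: float = 0.2
    use_bias: bool = True
    activation: str = "relu"  # applied between layers; final layer is linear

    def __post_init__(self):
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {AGGREGATORS}")
        if self.num_layers < 1 or self.hidden_dim < 1:
            raise ValueError("num_layers and hidden_dim must be >= 1")


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# batched graph container
# ---------------------------------------------------------------------------


@dataclass
class GraphBatch:
    """Block-diagonal stack of molecular graphs (all matrices constant)."""

    atom_features: np.ndarray  # n_atoms x F0
    pool: sparse.csr_matrix  # n_mols x n_atoms membership (sum pooling)
    adj_gcn: sparse.csr_matrix  # D^-1/2 (A+I) D^-1/2
    adj_mean: sparse.csr_matrix  # D^-1 A (zero rows for isolated atoms)
    adj_sym: sparse.csr_matrix  # D^-1/2 A D^-1/2 (no self loops)
    edge_src: np.ndarray  # directed edge list incl. self loops (for gat)
    edge_dst: np.ndarray
    scatter_dst: sparse.csr_matrix  # n_atoms x n_edges, 1 at (dst[e], e)

    @classmethod
    def from_molecules(cls, molecules: list[Molecule]) -> "GraphBatch":
        feats, blocks, sizes = [], [], []
        offset = 0
        rows_u, cols_u = [], []
        for mol in molecules:
            g = mol.graph
            feats.append(g.atom_features)
            sizes.append(g.num_atoms)
            for i, j in g.edges:
                rows_u.append(offset + i)
                cols_u.append(offset + j)
            offset += g.num_atoms
        n = offset
        x = np.concatenate(feats, axis=0) if feats else np.zeros((0, 0))
        # undirected adjacency
        r = np.array(rows_u + cols_u, dtype=np.intp)
        c = np.array(cols_u + rows_u, dtype=np.intp)
        adj = sparse.csr_matrix(
            (np.ones(len(r)), (r, c)), shape=(n, n)
        )
        deg = np.asarray(adj.sum(axis=1)).ravel()

        with np.errstate(divide="ignore"):
            d_self = 1.0 / np.sqrt(deg + 1.0)
            d_inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
            d_half = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1)), 0.0)
        eye = sparse.identity(n, format="csr")
        adj_gcn = sparse.diags(d_self) @ (adj + eye) @ sparse.diags(d_self)
        adj_mean = sparse.diags(d_inv) @ adj
        adj_sym = sparse.diags(d_half) @ adj @ sparse.diags(d_half)

        # directed edges incl. self loops for attention
        src = np.concatenate([r, np.arange(n, dtype=np.intp)])
        dst = np.concatenate([c, np.arange(n, dtype=np.intp)])
        scatter_dst = sparse.csr_matrix(
            (np.ones(len(dst)), (dst, np.arange(len(dst)))), shape=(n, len(dst))
        )

        mol_index = np.repeat(np.arange(len(molecules), dtype=np.intp), sizes)
        pool = sparse.csr_matrix(
            (np.ones(n), (mol_index, np.arange(n))), shape=(len(molecules), n)
        )
        return cls(x, pool, adj_gcn.tocsr(), adj_mean.tocsr(), adj_sym.tocsr(),
                   src, dst, scatter_dst)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


class MolecularGraphEncoder:
    """K-layer message-passing encoder with sum pooling (h^A)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        if config.input_dim < 1:
            raise ValueError("config.input_dim must be set before building params")
        self.config = config
        d = config.hidden_dim
        self.w_in = Parameter(glorot(rng, config.input_dim, d))
        self.layers: list[dict[str, Parameter]] = []
        for _ in range(config.num_layers):
            layer: dict[str, Parameter] = {}
            if config.aggregator == "gcn":
                layer["w"] = Parameter(glorot(rng, d, d))
            elif config.aggregator == "sage":
                layer["w_self"] = Parameter(glorot(rng, d, d))
                layer["w_neigh"] = Parameter(glorot(rng, d, d))
            elif config.aggregator == "gat":
                layer["w"] = Parameter(glorot(rng, d, d))
                layer["a_src"] = Parameter(glorot(rng, d, 1)[:, 0])
                layer["a_dst"] = Parameter(glorot(rng, d, 1)[:, 0])
            elif config.aggregator == "tag":
                for k in range(config.tag_hops + 1):
                    layer[f"w{k}"] = Parameter(glorot(rng, d, d))
            if config.use_bias:
                layer["b"] = Parameter(np.zeros(d))
            self.layers.append(layer)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = [self.w_in]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def _activate(self, x: Tensor) -> Tensor:
        if self.config.activation == "relu":
            return x.relu()
        if self.config.activation == "tanh":
            return x.tanh()
        raise ValueError(f"unknown activation {self.config.activation}")

    # -- layers ---------------------------------------------------------------
    def aggregate_layer(self, h: Tensor, layer: dict, batch: GraphBatch) -> Tensor:
        """Apply one aggregator update (self node included in every rule)."""
        agg = self.config.aggregator
        if agg == "gcn":
            out = sparse_mm(batch.adj_gcn, h) @ layer["w"]
        elif agg == "sage":
            out = h @ layer["w_self"] + sparse_mm(batch.adj_mean, h) @ layer["w_neigh"]
        elif agg == "tag":
            out = h @ layer["w0"]
            prop = h
            for k in range(1, self.config.tag_hops + 1):
                prop = sparse_mm(batch.adj_sym, prop)
                out = out + prop @ layer[f"w{k}"]
        elif agg == "gat":
            out = self._gat_forward(h, layer, batch)
        if "b" in layer:
            out = out + layer["b"]
        return out

    def _gat_forward(self, h: Tensor, layer: dict, batch: GraphBatch) -> Tensor:
        wh = h @ layer["w"]
        score_src = wh @ layer["a_src"]  # n_atoms
        score_dst = wh @ layer["a_dst"]
        logits = (
            score_src.take_rows(batch.edge_src) + score_dst.take_rows(batch.edge_dst)
        ).leaky_relu(self.config.leaky_slope)
        # per-destination softmax over incoming edges, stabilized by a
        # constant per-node max shift
        n = wh.data.shape[0]
        node_max = np.full(n, -np.inf)
        np.maximum.at(node_max, batch.edge_dst, logits.data)
        ex = (logits - node_max[batch.edge_dst]).exp()
        denom = sparse_mm(batch.scatter_dst, ex.reshape(-1, 1)).reshape(-1)
        alpha = ex / denom.take_rows(batch.edge_dst)
        messages = alpha.reshape(-1, 1) * wh.take_rows(batch.edge_src)
        return sparse_mm(batch.scatter_dst, messages)

    # -- public API -----------------------------------------------------------
    def atom_states(self, batch: GraphBatch) -> Tensor:
        """Run all K layers; returns the final per-atom state matrix."""
        h = Tensor(batch.atom_features) @ self.w_in
        for li, layer in enumerate(self.layers):
            h = self.aggregate_layer(h, layer, batch)
            if li < len(self.layers) - 1:  # final layer stays linear
                h = self._activate(h)
        return h

    def encode(self, batch: GraphBatch) -> Tensor:
        """Per-molecule h^A: sum pooling of final atom states."""
        return sparse_mm(batch.pool, self.atom_states(batch))

    def encode_molecules(self, molecules: list[Molecule]) -> Tensor:
        return self.encode(GraphBatch.from_molecules(molecules))
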