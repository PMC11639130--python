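"""Reaction-aware graph construction and encoding.

The reaction-aware graph is a molecule-level graph: nodes are the unique
molecules appearing in a reaction corpus and an edge joins every
(reactant, product) pair of every reaction, tagged with the originating
reaction. Encoding propagates functional-group-derived node features
along these edges with a reaction-context attention mechanism: the
attention logit for an edge is a learned linear score of the elementwise
product m_i ⊙ m_j ⊙ c, where c is the summed representation of all
molecules participating in the edge's reaction. The layer-L state of a
node is its reaction-level representation h^X.

Edges are traversed undirected (products inform reactants and vice
versa); the reactant→product orientation is kept as metadata only. When
a node's degree exceeds the sampling budget Q a uniform subset without
replacement is used; smaller neighborhoods are padded by sampling with
replacement so attention always normalizes over exactly Q draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .autodiff import Parameter, Tensor, softmax, sparse_mm
from .chemio import Molecule, ReactionRecord
from .molgraph_encoder import glorot


@dataclass
class SamplerConfig:
    Q: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.Q < 1:
            raise ValueError("Q must be >= 1")


@dataclass
class ReactionAwareGraph:
    """Molecule nodes, reaction-tagged reactant-product edges."""

    molecules: list[Molecule]
    index: dict[str, int]  # canonical SMILES -> node id
    edges: list[tuple[int, int, int]]  # (reactant_node, product_node, reaction_id)
    neighbors: list[list[tuple[int, int]]]  # node -> [(neighbor, reaction_id)]
    fg_counts: np.ndarray  # n_nodes x 39
    reaction_members: sparse.csr_matrix  # n_reactions x n_nodes, R ∪ P membership
    n_reactions: int

    @property
    def num_nodes(self) -> int:
        return len(self.molecules)

    def degree(self, node: int) -> int:
        return len(self.neighbors[node])

    def contains(self, smiles: str) -> bool:
        return smiles in self.index


def build_reaction_aware_graph(records: list[ReactionRecord]) -> ReactionAwareGraph:
    """Build the molecule-relation graph from a reaction corpus.

    One edge is created per (reactant, product) pair per reaction, so a
    reaction with |R|=a and |P|=b contributes exactly a*b edges; a
    molecule pair connected by several reactions keeps one edge per
    reaction. Nodes are deduplicated globally by canonical SMILES.
    """
    if not records:
        raise ValueError("cannot build a reaction-aware graph from zero reactions")
    molecules: list[Molecule] = []
    index: dict[str, int] = {}

    def node_of(mol: Molecule) -> int:
        i = index.get(mol.canonical_smiles)
        if i is None:
            i = len(molecules)
            index[mol.canonical_smiles] = i
            molecules.append(mol)
        return i

    edges: list[tuple[int, int, int]] = []
    member_rows: list[int] = []
    member_cols: list[int] = []
    for rid, rec in enumerate(records):
        r_nodes = [node_of(m) for m in rec.reactants]
        p_nodes = [node_of(m) for m in rec.products]
        for u in r_nodes:
            for v in p_nodes:
                edges.append((u, v, rid))
        for node in dict.fromkeys(r_nodes + p_nodes):
            member_rows.append(rid)
            member_cols.append(node)

    n = len(molecules)
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for u, v, rid in edges:
        neighbors[u].append((v, rid))
        neighbors[v].append((u, rid))
    members = sparse.csr_matrix(
        (np.ones(len(member_rows)), (member_rows, member_cols)),
        shape=(len(records), n),
    )
    fg_counts = np.stack([m.fg_vector for m in molecules]).astype(np.float64)
    return ReactionAwareGraph(
        molecules=molecules,
        index=index,
        edges=edges,
        neighbors=neighbors,
        fg_counts=fg_counts,
        reaction_members=members,
        n_reactions=len(records),
    )


def write_edge_list(graph: ReactionAwareGraph, path: str | Path) -> None:
    """Serialize edges as TSV: reactant_smiles, product_smiles, reaction_id."""
    lines = [
        f"{graph.molecules[u].canonical_smiles}\t"
        f"{graph.molecules[v].canonical_smiles}\t{rid}"
        for u, v, rid in graph.edges
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def sample_neighbors(
    graph: ReactionAwareGraph, node: int, Q: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Fixed-size neighbor sample for one node.

    Degree >= Q: uniform without replacement. 0 < degree < Q: with
    replacement up to Q. Degree 0: empty (aggregation falls back to the
    self term alone).
    """
    nbrs = graph.neighbors[node]
    if not nbrs:
        return []
    if len(nbrs) >= Q:
        picks = rng.choice(len(nbrs), size=Q, replace=False)
    else:
        picks = rng.choice(len(nbrs), size=Q, replace=True)
    return [nbrs[i] for i in picks]


@dataclass
class NeighborSample:
    """A full-graph neighbor draw, flattened for vectorized aggregation."""

    active: np.ndarray  # node ids with degree > 0
    src: np.ndarray  # (n_active*Q,) repeated node ids
    dst: np.ndarray  # (n_active*Q,) sampled neighbor ids
    rid: np.ndarray  # (n_active*Q,) reaction id per sampled edge
    Q: int
    scatter_active: sparse.csr_matrix  # n_nodes x n_active


def draw_neighbor_sample(
    graph: ReactionAwareGraph, config: SamplerConfig, rng: np.random.Generator | None = None
) -> NeighborSample:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    active, src, dst, rid = [], [], [], []
    for node in range(graph.num_nodes):
        sampled = sample_neighbors(graph, node, config.Q, rng)
        if not sampled:
            continue
        active.append(node)
        for j, r in sampled:
            src.append(node)
            dst.append(j)
            rid.append(r)
    active_arr = np.asarray(active, dtype=np.intp)
    scatter = sparse.csr_matrix(
        (np.ones(len(active_arr)), (active_arr, np.arange(len(active_arr)))),
        shape=(graph.num_nodes, len(active_arr)),
    )
    return NeighborSample(
        active=active_arr,
        src=np.asarray(src, dtype=np.intp),
        dst=np.asarray(dst, dtype=np.intp),
        rid=np.asarray(rid, dtype=np.intp),
        Q=config.Q,
        scatter_active=scatter,
    )


def attention_scores(
    m_i: Tensor, neighbors: Tensor, context: Tensor, w_a: Tensor
) -> Tensor:
    """Softmax attention over one node's sampled neighbors.

    Logit for neighbor j is w_a · (m_i ⊙ m_j ⊙ c). An empty neighbor set
    yields an empty distribution (no normalization attempted).
    """
    if neighbors.shape[0] == 0:
        return Tensor(np.zeros(0))
    prod = m_i.reshape(1, -1) * neighbors * context.reshape(1, -1)
    return softmax(prod @ w_a, axis=0)


@dataclass
class ReactionEncoderConfig:
    num_layers: int = 1
    hidden_dim: int = 256
    Q: int = 10

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


class ReactionAwareEncoder:
    """L-layer reaction-context attention GNN over the reaction-aware graph.

    Node features start as the sum of functional-group embeddings (a
    learned 39 x d table contracted with the group-count vector), and
    each layer adds attention-weighted neighbor states to the node's own
    state. Molecules absent from the graph fall back to their projected
    functional-group vector.
    """

    def __init__(self, config: ReactionEncoderConfig, rng: np.random.Generator,
                 n_fg: int = 39):
        self.config = config
        d = config.hidden_dim
        self.fg_embedding = Parameter(glorot(rng, n_fg, d))
        self.w_a = [Parameter(glorot(rng, d, 1)[:, 0]) for _ in range(config.num_layers)]

    def parameters(self) -> list[Parameter]:
        return [self.fg_embedding, *self.w_a]

    def initial_states(self, graph: ReactionAwareGraph) -> Tensor:
        return Tensor(graph.fg_counts) @ self.fg_embedding

    def aggregate_layer(
        self,
        graph: ReactionAwareGraph,
        states: Tensor,
        sample: NeighborSample,
        layer: int,
    ) -> Tensor:
        """One synchronous update m^l = m^{l-1} + Σ_j π_ij m_j^{l-1}.

        Attention for edge (i, j) uses the context of the reaction that
        created the edge: the sum of layer-(l-1) states over that
        reaction's participants.
        """
        if len(sample.active) == 0:
            return states
        context = sparse_mm(graph.reaction_members, states)  # n_reactions x d
        m_i = states.take_rows(sample.src)
        m_j = states.take_rows(sample.dst)
        c = context.take_rows(sample.rid)
        logits = ((m_i * m_j * c) @ self.w_a[layer]).reshape(-1, sample.Q)
        pi = softmax(logits, axis=1)  # n_active x Q
        weighted = pi.reshape(-1, 1) * m_j
        agg = weighted.reshape(len(sample.active), sample.Q, -1).sum(axis=1)
        return states + sparse_mm(sample.scatter_active, agg)

    def encode(
        self, graph: ReactionAwareGraph, sample: NeighborSample | None = None,
        rng: np.random.Generator | None = None, seed: int = 0
    ) -> Tensor:
        """Per-node h^X = m^L for every molecule in the graph."""
        if sample is None:
            sample = draw_neighbor_sample(
                graph, SamplerConfig(Q=self.config.Q, seed=seed), rng
            )
        states = self.initial_states(graph)
        for layer in range(self.config.num_layers):
            states = self.aggregate_layer(graph, states, sample, layer)
        return states

    def fallback_embedding(self, molecules: list[Molecule]) -> Tensor:
        """Projected functional-group counts for out-of-graph molecules."""
        counts = np.stack([m.fg_vector for m in molecules]).astype(np.float64)
        return Tensor(counts) @ self.fg_embedding
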