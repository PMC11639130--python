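"""The full dual-graph relation-learning model.

Ties together the molecular-graph encoder (h^A), the reaction-aware
encoder (h^X), the fusion map h = Wc(h^A || h^X) and the relation memory
network, over a fixed reaction-aware graph built from the training
corpus only. Molecules outside that graph (validation/test-only
molecules) receive the functional-group fallback for the reaction view;
their count is surfaced in the embedding metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .autodiff import Parameter, Tensor, concat, sparse_mm
from .chemio import FeatureVocab, Molecule, ReactionRecord
from .molgraph_encoder import EncoderConfig, GraphBatch, MolecularGraphEncoder, glorot
from .objectives import LossConfig
from .reaction_graph import (
    NeighborSample,
    ReactionAwareEncoder,
    ReactionAwareGraph,
    ReactionEncoderConfig,
    SamplerConfig,
    build_reaction_aware_graph,
    draw_neighbor_sample,
)
from .relation_memory import MemoryConfig, RelationMemory


@dataclass
class ModelConfig:
    dim: int = 256
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    rxgraph: ReactionEncoderConfig = field(default_factory=ReactionEncoderConfig)
    memory: MemoryConfig = field(default_factory=MemoryConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self):
        # one shared embedding width across modules
        self.encoder.hidden_dim = self.dim
        self.rxgraph.hidden_dim = self.dim
        self.memory.hidden_dim = self.dim


@dataclass
class SideEmbeddings:
    """Per-reaction side embeddings (numpy, inference-time)."""

    x_r: np.ndarray
    x_p: np.ndarray
    xr_a: np.ndarray
    xr_x: np.ndarray
    xp_a: np.ndarray
    xp_x: np.ndarray
    n_fallback: int  # molecules that used the out-of-graph fallback


def _side_incidence(records, index: dict[str, int], side: str, n_cols: int):
    rows, cols = [], []
    for i, rec in enumerate(records):
        for smi in getattr(rec, f"{side}_smiles"):
            rows.append(i)
            cols.append(index[smi])
    return sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(records), n_cols)
    )


class RXGLModel:
    def __init__(
        self,
        train_records: list[ReactionRecord],
        vocab: FeatureVocab,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.vocab = vocab
        rng = np.random.default_rng(self.config.seed)
        self.graph: ReactionAwareGraph = build_reaction_aware_graph(train_records)
        self.graph_batch = GraphBatch.from_molecules(self.graph.molecules)

        enc_cfg = self.config.encoder
        # width comes from the parsed molecules themselves so the model
        # always matches the vocabulary the corpus was featurized with
        enc_cfg.input_dim = self.graph_batch.atom_features.shape[1]
        if enc_cfg.input_dim != vocab.width:
            raise ValueError(
                f"corpus was featurized with width {enc_cfg.input_dim} but the "
                f"supplied vocabulary has width {vocab.width}; parse the corpus "
                "with the same FeatureVocab given to the model"
            )
        self.mol_encoder = MolecularGraphEncoder(enc_cfg, rng)
        self.rx_encoder = ReactionAwareEncoder(self.config.rxgraph, rng)
        d = self.config.dim
        self.w_c = Parameter(glorot(rng, 2 * d, d))
        self.memory = RelationMemory(self.config.memory, rng)

    def parameters(self) -> list[Parameter]:
        return (
            self.mol_encoder.parameters()
            + self.rx_encoder.parameters()
            + [self.w_c]
            + self.memory.parameters()
        )

    # -- differentiable forward (training path) ------------------------------
    def node_tables(self, sample: NeighborSample) -> tuple[Tensor, Tensor, Tensor]:
        """(h^A, h^X, fused h) for every node of the training graph."""
        h_a = self.mol_encoder.encode(self.graph_batch)
        h_x = self.rx_encoder.encode(self.graph, sample=sample)
        h = concat([h_a, h_x], axis=1) @ self.w_c
        return h_a, h_x, h

    def batch_embeddings(self, records: list[ReactionRecord], sample: NeighborSample):
        """Differentiable side embeddings for a batch of training reactions."""
        h_a, h_x, h = self.node_tables(sample)
        n = self.graph.num_nodes
        r_inc = _side_incidence(records, self.graph.index, "reactant", n)
        p_inc = _side_incidence(records, self.graph.index, "product", n)
        return {
            "x_r": sparse_mm(r_inc, h),
            "x_p": sparse_mm(p_inc, h),
            "xr_a": sparse_mm(r_inc, h_a),
            "xr_x": sparse_mm(r_inc, h_x),
            "xp_a": sparse_mm(p_inc, h_a),
            "xp_x": sparse_mm(p_inc, h_x),
        }

    def draw_sample(self, seed: int) -> NeighborSample:
        return draw_neighbor_sample(
            self.graph, SamplerConfig(Q=self.config.rxgraph.Q, seed=seed)
        )

    # -- inference path (numpy) ----------------------------------------------
    def molecule_views(self, molecules: list[Molecule], sample_seed: int = 0):
        """(h^A, h^X, fused h) rows for arbitrary molecules, no gradients.

        Graph members get their trained reaction-view state; others fall
        back to the projected functional-group vector.
        """
        h_a = self.mol_encoder.encode_molecules(molecules).data
        hx_graph = self.rx_encoder.encode(self.graph, seed=sample_seed).data
        fallback = self.rx_encoder.fallback_embedding(molecules).data
        h_x = np.empty_like(h_a)
        n_fallback = 0
        for i, mol in enumerate(molecules):
            j = self.graph.index.get(mol.canonical_smiles)
            if j is None:
                h_x[i] = fallback[i]
                n_fallback += 1
            else:
                h_x[i] = hx_graph[j]
        h = np.concatenate([h_a, h_x], axis=1) @ self.w_c.data
        return h_a, h_x, h, n_fallback

    def embed_reactions(
        self, records: list[ReactionRecord], sample_seed: int = 0
    ) -> SideEmbeddings:
        mols: dict[str, Molecule] = {}
        for rec in records:
            for m in (*rec.reactants, *rec.products):
                mols.setdefault(m.canonical_smiles, m)
        mol_list = list(mols.values())
        index = {m.canonical_smiles: i for i, m in enumerate(mol_list)}
        h_a, h_x, h, n_fallback = self.molecule_views(mol_list, sample_seed)
        r_inc = _side_incidence(records, index, "reactant", len(mol_list))
        p_inc = _side_incidence(records, index, "product", len(mol_list))
        return SideEmbeddings(
            x_r=r_inc @ h,
            x_p=p_inc @ h,
            xr_a=r_inc @ h_a,
            xr_x=r_inc @ h_x,
            xp_a=p_inc @ h_a,
            xp_x=p_inc @ h_x,
            n_fallback=n_fallback,
        )

    def pairwise_scores_np(self, x_r: np.ndarray, x_p: np.ndarray) -> np.ndarray:
        """Inference-time S(R_i, P_j) matrix (relation vector per pair)."""
        return self.memory.pairwise_scores(Tensor(x_r), Tensor(x_p)).data

    def relation_vectors_np(self, x_r: np.ndarray, x_p: np.ndarray) -> np.ndarray:
        """Aligned per-reaction relation vectors e_{R_i → P_i}."""
        return self.memory.relation(Tensor(x_r), Tensor(x_p)).data

    # -- parameter snapshots ---------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, arr in zip(self.parameters(), state, strict=True):
            p.data = arr.copy()

    def save(self, directory: str | Path, train_records=None) -> None:
        """Persist parameters, config and vocabulary to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "params.npz",
            **{f"p{i}": p.data for i, p in enumerate(self.parameters())},
        )
        meta = {
            "dim": self.config.dim,
            "seed": self.config.seed,
            "encoder": asdict(self.config.encoder),
            "rxgraph": asdict(self.config.rxgraph),
            "memory": asdict(self.config.memory),
            "loss": asdict(self.config.loss),
            "vocab_elements": list(self.vocab.elements),
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        if train_records is not None:
            from .chemio import write_reaction_file

            write_reaction_file(train_records, directory / "train_reactions.txt")

    @classmethod
    def load(cls, directory: str | Path) -> "RXGLModel":
        from .chemio import read_reaction_file

        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        vocab = FeatureVocab(elements=tuple(meta["vocab_elements"]))
        enc = EncoderConfig(**meta["encoder"])
        cfg = ModelConfig(
            dim=meta["dim"],
            encoder=enc,
            rxgraph=ReactionEncoderConfig(**meta["rxgraph"]),
            memory=MemoryConfig(**meta["memory"]),
            loss=LossConfig(**meta["loss"]),
            seed=meta["seed"],
        )
        records, _ = read_reaction_file(directory / "train_reactions.txt", vocab=vocab)
        model = cls(records, vocab, cfg)
        data = np.load(directory / "params.npz")
        model.load_state([data[f"p{i}"] for i in range(len(model.parameters()))])
        return model
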