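"""Dual-view fusion and the reactant→product relation memory network.

A molecule's fused embedding is h = Wc (h^A || h^X). A reaction side is
the sum of its members' fused embeddings. The relation vector for a
(reactant-side, product-side) pair is produced by a key/memory network:
keys score the elementwise product xR ⊙ xP into a softmax attention over
N slots, and the relation vector is the attention-weighted combination
of the memory rows — so e always lies in the convex hull of the memory
rows, and with a single slot the model degenerates to one global
translation (plain TransE). The pair is scored by how well the
translation closes the triangle: S = ||xR + e − xP||², with a plain-norm
variant behind a switch (rankings coincide within one convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat, softmax

SCORE_NORMS = ("squared", "l2")


@dataclass
class MemoryConfig:
    n_slots: int = 10
    hidden_dim: int = 256
    score_norm: str = "squared"

    def __post_init__(self):
        if self.n_slots < 1:
            raise ValueError("n_slots must be >= 1")
        if self.score_norm not in SCORE_NORMS:
            raise ValueError(f"score_norm must be one of {SCORE_NORMS}")


def fuse(h_a: Tensor, h_x: Tensor, w_c: Tensor) -> Tensor:
    """Fused molecule embedding h = Wc (h^A || h^X).

    Inputs are (n, d) matrices; w_c maps 2d -> d and is stored as a
    (2d, d) matrix applied on the right.
    """
    if h_a.shape != h_x.shape:
        raise ValueError(f"view shapes differ: {h_a.shape} vs {h_x.shape}")
    both = concat([h_a, h_x], axis=1)
    if both.shape[1] != w_c.shape[0]:
        raise ValueError(
            f"fusion weight expects input dim {w_c.shape[0]}, got {both.shape[1]}"
        )
    return both @ w_c


def side_embedding(member_rows: Tensor) -> Tensor:
    """Reaction-side embedding: the sum of member molecule embeddings."""
    if member_rows.shape[0] == 0:
        raise ValueError("a reaction side cannot be empty")
    return member_rows.sum(axis=0)


class RelationMemory:
    """Key/memory attention network producing per-pair relation vectors."""

    def __init__(self, config: MemoryConfig, rng: np.random.Generator):
        self.config = config
        n, d = config.n_slots, config.hidden_dim
        # scale 1/sqrt(d) keeps the key logits O(1) at initialization
        self.keys = Parameter(rng.standard_normal((n, d)) / np.sqrt(d))
        self.memory = Parameter(rng.standard_normal((n, d)) / np.sqrt(d))

    def parameters(self) -> list[Parameter]:
        return [self.keys, self.memory]

    def attention(self, x_r: Tensor, x_p: Tensor) -> Tensor:
        """Slot attention att_n = softmax_n((xR ⊙ xP)ᵀ k_n).

        Accepts single vectors (d,) or stacks (..., d); attention is
        taken over the slot axis appended last.
        """
        return softmax((x_r * x_p) @ self.keys.T, axis=-1)

    def relation_vector(self, att: Tensor) -> Tensor:
        """e = Σ_n att_n m_n — a convex combination of memory rows."""
        return att @ self.memory

    def relation(self, x_r: Tensor, x_p: Tensor) -> Tensor:
        return self.relation_vector(self.attention(x_r, x_p))

    def score(self, x_r: Tensor, x_p: Tensor) -> Tensor:
        """Translation score S(R, P) for aligned reactant/product stacks."""
        e = self.relation(x_r, x_p)
        return score_from_relation(x_r, x_p, e, self.config.score_norm)

    def pairwise_scores(self, x_r: Tensor, x_p: Tensor) -> Tensor:
        """Score every (reactant-side i, product-side j) combination.

        Returns an (nR, nP) matrix; each pair gets its own relation
        vector because the memory network conditions on both sides.
        """
        n_r, d = x_r.shape
        n_p = x_p.shape[0]
        z = x_r.reshape(n_r, 1, d) * x_p.reshape(1, n_p, d)
        att = softmax(z @ self.keys.T, axis=-1)  # nR x nP x N
        e = att @ self.memory  # nR x nP x d
        diff = x_r.reshape(n_r, 1, d) + e - x_p.reshape(1, n_p, d)
        sq = diff.norm_sq(axis=-1)
        return sq if self.config.score_norm == "squared" else (sq + 1e-300) ** 0.5


def score_from_relation(
    x_r: Tensor, x_p: Tensor, e: Tensor, score_norm: str = "squared"
) -> Tensor:
    """S = ||xR + e − xP||² (or its square root under the l2 convention)."""
    if score_norm not in SCORE_NORMS:
        raise ValueError(f"score_norm must be one of {SCORE_NORMS}")
    sq = (x_r + e - x_p).norm_sq(axis=-1)
    return sq if score_norm == "squared" else (sq + 1e-300) ** 0.5
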