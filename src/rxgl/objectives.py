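"""Training objectives.

Three pieces combine into the total loss L = LE + α·LC + λ·||Θ||²_F:

* the margin relation loss LE pulls each reaction's matched
  reactant/product pair toward a zero translation score while pushing
  every in-batch mismatched (i, j) pair, both orders, at least a margin
  γ away;
* the cross-view contrastive loss LC is InfoNCE over cosine
  similarities between the molecular-graph-view and reaction-graph-view
  side embeddings, computed separately for reactant sides and product
  sides and summed;
* an optional Frobenius regularizer over all learnable parameters.

Negatives are exactly the in-batch mismatches; epoch-level shuffling of
the training reactions refreshes them every epoch, so no negative store
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, log_softmax

EPS_NORM = 1e-12


@dataclass
class LossConfig:
    gamma: float = 4.0  # margin
    tau: float = 0.1  # InfoNCE temperature
    alpha: float = 1e-3  # contrastive weight
    l2: float = 0.0  # λ; no value is fixed upstream, off by default

    def __post_init__(self):
        if self.gamma <= 0 or self.tau <= 0:
            raise ValueError("gamma and tau must be positive")
        if self.alpha < 0 or self.l2 < 0:
            raise ValueError("alpha and l2 must be non-negative")


def margin_loss(pairwise: Tensor, gamma: float) -> Tensor:
    """Margin relation loss over a batch's full score matrix.

    ``pairwise[i, j]`` is S(R_i, P_j). The positive term averages the
    diagonal; the negative term averages max(γ − S, 0) over the
    |XB|² − |XB| ordered off-diagonal pairs. A single-reaction batch has
    no negatives and the second term is zero. Colliding product sides
    (P_j equal to P_i as a set) are still treated as negatives; callers
    may count them separately.
    """
    b = pairwise.shape[0]
    if pairwise.shape != (b, b):
        raise ValueError("pairwise score matrix must be square")
    eye = np.eye(b)
    positive = (pairwise * eye).sum() / float(b)
    if b == 1:
        return positive
    hinge = (gamma - pairwise).relu() * (1.0 - eye)
    negative = hinge.sum() / float(b * b - b)
    return positive + negative


def view_side_embeddings(
    member_index: Sequence[int], view_table: Tensor
) -> Tensor:
    """Sum the per-view embeddings of one reaction side's members."""
    if len(member_index) == 0:
        raise ValueError("a reaction side cannot be empty")
    return view_table.take_rows(np.asarray(member_index, dtype=np.intp)).sum(axis=0)


def cosine_matrix(a: Tensor, b: Tensor) -> Tensor:
    """All-pairs cosine similarity between rows of a and rows of b."""
    norms_a = a.norm(axis=1, eps=0.0)
    norms_b = b.norm(axis=1, eps=0.0)
    if np.any(norms_a.data < EPS_NORM) or np.any(norms_b.data < EPS_NORM):
        raise ValueError("cosine similarity undefined for zero-norm embedding")
    sims = a @ b.T
    return sims / (norms_a.reshape(-1, 1) * norms_b.reshape(1, -1))


def infonce_loss(view_a: Tensor, view_x: Tensor, tau: float) -> Tensor:
    """InfoNCE across views for one reaction side.

    Anchor i (view A) is matched against its own view-X embedding and
    contrasted with every other reaction's view-X embedding in the
    batch; the loss is the summed cross-entropy of the row-softmaxed
    similarity matrix against the identity pairing. A batch of one gives
    exactly zero.
    """
    sims = cosine_matrix(view_a, view_x)
    logp = log_softmax(sims / tau, axis=1)
    b = sims.shape[0]
    return -(logp * np.eye(b)).sum()


def cross_view_loss(
    xr_a: Tensor, xr_x: Tensor, xp_a: Tensor, xp_x: Tensor, tau: float
) -> Tensor:
    """LC = reactant-side InfoNCE + product-side InfoNCE."""
    return infonce_loss(xr_a, xr_x, tau) + infonce_loss(xp_a, xp_x, tau)


def l2_penalty(params: Sequence) -> Tensor:
    total = Tensor(0.0)
    for p in params:
        total = total + (p * p).sum()
    return total


def total_loss(
    le: Tensor, lc: Tensor, params: Sequence, alpha: float, lam: float
) -> Tensor:
    """L = LE + α·LC + λ·||Θ||²_F over all learnable parameters Θ."""
    out = le + alpha * lc
    if lam > 0:
        out = out + lam * l2_penalty(params)
    return out
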