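"""Training orchestration and the downstream evaluation protocols.

Training minimizes the combined objective over shuffled minibatches of
reactions; negatives are the in-batch mismatches and are refreshed every
epoch by the shuffle. Model selection keeps the parameter snapshot with
the best validation mean reciprocal rank.

Evaluations:

* product ranking — every test reaction's reactant side is scored
  against the product sides of *all* test reactions (the candidate
  pool), a fresh relation vector per candidate; lower score is better
  and ties count against the true candidate;
* reaction classification — the concatenated (xR, xP) pair embedding is
  fed to a small MLP decoder trained separately;
* property prediction — the molecule transfer feature is h^A
  concatenated with the summed functional-group embedding (the reaction
  view is deliberately not used, so unseen molecules embed cleanly),
  scored with logistic regression;
* relation analysis — per-reaction relation vectors compared by cosine
  against the difference in bond-count and ring-count changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .chemio import DatasetSplit, Molecule, ReactionRecord
from .model import RXGLModel
from .objectives import cross_view_loss, margin_loss, total_loss

_MAX_SEED = 2**31 - 1


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 1024
    learning_rate: float = 1e-4
    seed: int = 0
    log_path: str | None = None  # JSON-lines per-epoch log

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError("epochs, batch_size must be >= 1; learning_rate >= 0")


@dataclass
class RankingResult:
    ranks: np.ndarray  # 1-based rank of the true product side per reaction
    n_candidates: int

    @property
    def mrr(self) -> float:
        return float(np.mean(1.0 / self.ranks))

    @property
    def hit1(self) -> float:
        return float(np.mean(self.ranks == 1))


@dataclass
class TrainResult:
    model: RXGLModel
    loss_trace: list[dict]
    best_epoch: int
    best_val_mrr: float


def rank_products(
    model: RXGLModel, test_records: list[ReactionRecord], sample_seed: int = 0
) -> RankingResult:
    """Rank all test product sides against each test reactant side.

    Candidate j for reaction i is scored with S(R_i, P_j); the true
    candidate's rank uses pessimistic tie-breaking (placed after every
    equal-scored competitor). Duplicate product sides stay distinct
    candidates.
    """
    if not test_records:
        raise ValueError("no test reactions to rank")
    emb = model.embed_reactions(test_records, sample_seed=sample_seed)
    scores = model.pairwise_scores_np(emb.x_r, emb.x_p)
    return ranking_from_scores(scores)


def ranking_from_scores(scores: np.ndarray) -> RankingResult:
    """Ranks from an (n, n) score matrix whose diagonal is the truth."""
    n = scores.shape[0]
    true_scores = np.diag(scores)
    better = (scores < true_scores[:, None]).sum(axis=1)
    tied = (scores == true_scores[:, None]).sum(axis=1) - 1  # exclude self
    ranks = 1 + better + tied  # pessimistic: true candidate after ties
    return RankingResult(ranks=ranks.astype(np.int64), n_candidates=n)


def _epoch_seed(base: int, epoch: int) -> int:
    return (base * 1_000_003 + epoch) % _MAX_SEED


def train(
    split: DatasetSplit,
    model: RXGLModel,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Optimize the combined objective; checkpoint on best validation MRR."""
    config = config or TrainConfig()
    loss_cfg = model.config.loss
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    records = list(split.train)
    best_state = model.state_dict()
    best_val = -np.inf
    best_epoch = -1
    trace: list[dict] = []
    log_fh = open(config.log_path, "w") if config.log_path else None
    try:
        for epoch in range(config.epochs):
            eseed = _epoch_seed(config.seed, epoch)
            order = np.random.default_rng(eseed).permutation(len(records))
            sample = model.draw_sample(seed=eseed)
            sums = {"le": 0.0, "lc": 0.0, "loss": 0.0}
            n_batches = 0
            for start in range(0, len(records), config.batch_size):
                batch = [records[i] for i in order[start : start + config.batch_size]]
                emb = model.batch_embeddings(batch, sample)
                pairwise = model.memory.pairwise_scores(emb["x_r"], emb["x_p"])
                le = margin_loss(pairwise, loss_cfg.gamma)
                lc = cross_view_loss(
                    emb["xr_a"], emb["xr_x"], emb["xp_a"], emb["xp_x"], loss_cfg.tau
                )
                loss = total_loss(le, lc, params, loss_cfg.alpha, loss_cfg.l2)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, "
                        f"batch starting at shuffled index {start}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                sums["le"] += float(le.data)
                sums["lc"] += float(lc.data)
                sums["loss"] += float(loss.data)
                n_batches += 1
            val_mrr = rank_products(model, split.valid, sample_seed=eseed).mrr
            entry = {
                "epoch": epoch,
                "LE": sums["le"] / n_batches,
                "LC": sums["lc"] / n_batches,
                "L": sums["loss"] / n_batches,
                "val_MRR": val_mrr,
            }
            trace.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
            if val_mrr > best_val:
                best_val = val_mrr
                best_epoch = epoch
                best_state = model.state_dict()
    finally:
        if log_fh:
            log_fh.close()
    model.load_state(best_state)
    return TrainResult(
        model=model, loss_trace=trace, best_epoch=best_epoch, best_val_mrr=best_val
    )


# ---------------------------------------------------------------------------
# transfer features
# ---------------------------------------------------------------------------


def reaction_features_for_classification(
    model: RXGLModel, records: list[ReactionRecord], sample_seed: int = 0
) -> np.ndarray:
    """Unified reaction feature: xR concatenated with xP (dim 2d)."""
    emb = model.embed_reactions(records, sample_seed=sample_seed)
    return np.concatenate([emb.x_r, emb.x_p], axis=1)


def molecule_features_for_property(
    model: RXGLModel, molecules: list[Molecule]
) -> np.ndarray:
    """Transfer feature: h^A || summed functional-group embedding.

    The reaction-graph view is not part of this feature, so molecules
    never seen in any reaction embed without a fallback path.
    """
    h_a = model.mol_encoder.encode_molecules(molecules).data
    counts = np.stack([m.fg_vector for m in molecules]).astype(np.float64)
    fg_sum = counts @ model.rx_encoder.fg_embedding.data
    return np.concatenate([h_a, fg_sum], axis=1)


def classify_reactions(
    model: RXGLModel,
    train_records: list[ReactionRecord],
    test_records: list[ReactionRecord],
    seed: int = 0,
    hidden: tuple[int, ...] = (128,),
) -> dict:
    """Train an MLP decoder on reaction features; report accuracy/recall."""
    from sklearn.metrics import accuracy_score, recall_score
    from sklearn.neural_network import MLPClassifier

    if any(r.label is None for r in (*train_records, *test_records)):
        raise ValueError("reaction classification requires labeled records")
    y_train = np.array([r.label for r in train_records])
    y_test = np.array([r.label for r in test_records])
    f_train = reaction_features_for_classification(model, train_records)
    f_test = reaction_features_for_classification(model, test_records)
    clf = MLPClassifier(
        hidden_layer_sizes=hidden, max_iter=500, random_state=seed
    ).fit(f_train, y_train.astype(int))
    pred = clf.predict(f_test)
    return {
        "accuracy": float(accuracy_score(y_test.astype(int), pred)),
        "recall_macro": float(
            recall_score(y_test.astype(int), pred, average="macro", zero_division=0)
        ),
        "recall_micro": float(
            recall_score(y_test.astype(int), pred, average="micro", zero_division=0)
        ),
    }


def predict_property(
    model: RXGLModel,
    train_mols: list[Molecule],
    train_labels: np.ndarray,
    test_mols: list[Molecule],
    test_labels: np.ndarray,
    seed: int = 0,
) -> dict:
    """Logistic regression on molecule transfer features; reports AUC."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    f_train = molecule_features_for_property(model, train_mols)
    f_test = molecule_features_for_property(model, test_mols)
    clf = LogisticRegression(max_iter=2000, random_state=seed).fit(
        f_train, train_labels
    )
    prob = clf.predict_proba(f_test)[:, 1]
    return {"auc": float(roc_auc_score(test_labels, prob))}


# ---------------------------------------------------------------------------
# relation-embedding analysis
# ---------------------------------------------------------------------------


@dataclass
class RelationAnalysis:
    cosine: np.ndarray  # per-pair cosine of relation vectors (condensed)
    bond_diff: np.ndarray  # |ΔNB_i − ΔNB_j| per pair
    ring_diff: np.ndarray  # |ΔNR_i − ΔNR_j| per pair
    bins: list[dict] = field(default_factory=list)  # binned summary


def relation_similarity_analysis(
    model: RXGLModel,
    records: list[ReactionRecord],
    sample_seed: int = 0,
    n_bins: int = 5,
) -> RelationAnalysis:
    """Compare relation-vector cosine with bond/ring-change differences.

    For every unordered reaction pair, computes the cosine similarity of
    their relation vectors and the absolute difference of their ΔNB and
    ΔNR; the binned summary gives the mean differences per cosine
    interval (the macro view of the relation-embedding semantics).
    """
    emb = model.embed_reactions(records, sample_seed=sample_seed)
    e = model.relation_vectors_np(emb.x_r, emb.x_p)
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    unit = e / np.maximum(norms, 1e-12)
    cos_full = unit @ unit.T
    dnb = np.array([r.delta_bonds for r in records], dtype=float)
    dnr = np.array([r.delta_rings for r in records], dtype=float)
    iu = np.triu_indices(len(records), k=1)
    cosine = cos_full[iu]
    bond_diff = np.abs(dnb[:, None] - dnb[None, :])[iu]
    ring_diff = np.abs(dnr[:, None] - dnr[None, :])[iu]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (cosine >= lo) & (cosine < hi if hi < 1.0 else cosine <= hi)
        bins.append(
            {
                "interval": (float(lo), float(hi)),
                "n_pairs": int(mask.sum()),
                "mean_bond_diff": float(bond_diff[mask].mean()) if mask.any() else float("nan"),
                "mean_ring_diff": float(ring_diff[mask].mean()) if mask.any() else float("nan"),
            }
        )
    return RelationAnalysis(
        cosine=cosine, bond_diff=bond_diff, ring_diff=ring_diff, bins=bins
    )


def family_cosine_summary(
    analysis: RelationAnalysis, families: np.ndarray
) -> dict[str, float]:
    """Mean within- vs between-family relation cosine for labeled corpora."""
    iu = np.triu_indices(len(families), k=1)
    same = families[iu[0]] == families[iu[1]]
    return {
        "within": float(analysis.cosine[same].mean()),
        "between": float(analysis.cosine[~same].mean()),
    }
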