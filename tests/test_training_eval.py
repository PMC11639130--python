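"""Training loop, ranking protocol, transfer features, relation analysis."""

import json

import numpy as np
import pytest

from rxgl.chemio import parse_molecule, split_dataset
from rxgl.model import ModelConfig, RXGLModel
from rxgl.training_eval import (
    RankingResult,
    TrainConfig,
    molecule_features_for_property,
    rank_products,
    ranking_from_scores,
    reaction_features_for_classification,
    relation_similarity_analysis,
    train,
)


@pytest.fixture()
def toy_split(toy_records):
    return split_dataset(toy_records, seed=0)


def _model(records, vocab, dim=8, seed=3):
    return RXGLModel(records, vocab, ModelConfig(dim=dim, seed=seed))


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, toy_split, vocab):
        model = _model(toy_split.train, vocab)
        before = model.state_dict()
        train(model=model, split=toy_split,
              config=TrainConfig(epochs=1, batch_size=4, learning_rate=0.0, seed=0))
        # checkpointing restores the (unchanged) best state
        for a, b in zip(before, model.state_dict()):
            np.testing.assert_array_equal(a, b)

    def test_same_seeds_give_identical_loss_traces(self, toy_split, vocab):
        traces = []
        for _ in range(2):
            model = _model(toy_split.train, vocab)
            res = train(model=model, split=toy_split,
                        config=TrainConfig(epochs=3, batch_size=4,
                                           learning_rate=1e-3, seed=9))
            traces.append(res.loss_trace)
        assert traces[0] == traces[1]

    def test_loss_decreases_on_200_reaction_corpus(self, small_split, vocab):
        model = _model(small_split.train, vocab, dim=32, seed=0)
        res = train(model=model, split=small_split,
                    config=TrainConfig(epochs=20, batch_size=64,
                                       learning_rate=1e-3, seed=0))
        assert res.loss_trace[-1]["L"] < res.loss_trace[0]["L"]
        assert res.best_epoch >= 0

    def test_epoch_log_is_json_lines(self, toy_split, vocab, tmp_path):
        log = tmp_path / "log.jsonl"
        model = _model(toy_split.train, vocab)
        train(model=model, split=toy_split,
              config=TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3,
                                 seed=0, log_path=str(log)))
        entries = [json.loads(line) for line in log.read_text().splitlines()]
        assert len(entries) == 2
        assert set(entries[0]) == {"epoch", "LE", "LC", "L", "val_MRR"}


class TestRanking:
    def test_single_reaction_perfect(self):
        res = ranking_from_scores(np.array([[0.3]]))
        assert res.mrr == 1.0 and res.hit1 == 1.0

    def test_strictly_best_diagonal_gives_mrr_one(self, rng):
        scores = rng.random((6, 6)) + 1.0
        np.fill_diagonal(scores, 0.0)
        assert ranking_from_scores(scores).mrr == 1.0

    def test_hand_mrr_arithmetic(self):
        # engineered ranks (1, 2, 2, 4) -> MRR (1 + .5 + .5 + .25)/4
        scores = np.full((4, 4), 9.0)
        scores[0, 0] = 0.0
        scores[1, 1], scores[1, 0] = 1.0, 0.5
        scores[2, 2], scores[2, 3] = 1.0, 0.5
        scores[3, 3], scores[3, 0], scores[3, 1], scores[3, 2] = 3.0, 1.0, 2.0, 2.5
        res = ranking_from_scores(scores)
        np.testing.assert_array_equal(res.ranks, [1, 2, 2, 4])
        assert res.mrr == pytest.approx(0.5625)

    def test_ties_count_against_the_true_candidate(self):
        scores = np.zeros((3, 3))  # every candidate tied with the truth
        res = ranking_from_scores(scores)
        np.testing.assert_array_equal(res.ranks, [3, 3, 3])

    def test_hit1_never_exceeds_mrr(self, rng):
        for _ in range(10):
            res = ranking_from_scores(rng.random((8, 8)))
            assert res.hit1 <= res.mrr

    def test_candidate_order_invariance(self, rng):
        scores = rng.random((7, 7))
        base = ranking_from_scores(scores).ranks
        perm = rng.permutation(7)
        permuted = ranking_from_scores(scores[np.ix_(perm, perm)]).ranks
        np.testing.assert_array_equal(permuted, base[perm])

    def test_rank_products_on_model(self, toy_split, vocab):
        model = _model(toy_split.train, vocab)
        res = rank_products(model, toy_split.test)
        assert isinstance(res, RankingResult)
        assert res.n_candidates == len(toy_split.test)
        assert 0.0 < res.mrr <= 1.0


class TestTransferFeatures:
    def test_reaction_feature_is_ordered_concatenation(self, toy_records, vocab):
        model = _model(toy_records, vocab)
        feats = reaction_features_for_classification(model, toy_records[:3])
        assert feats.shape == (3, 2 * model.config.dim)
        emb = model.embed_reactions(toy_records[:3])
        np.testing.assert_allclose(feats[:, : model.config.dim], emb.x_r)
        np.testing.assert_allclose(feats[:, model.config.dim :], emb.x_p)
        # identical reactions -> identical features; swapped sides differ
        again = reaction_features_for_classification(model, toy_records[:3])
        np.testing.assert_allclose(feats, again)
        swapped = np.concatenate([emb.x_p, emb.x_r], axis=1)
        assert not np.allclose(feats, swapped)

    def test_molecule_feature_layout_and_zero_fg_block(self, toy_records, vocab):
        model = _model(toy_records, vocab)
        ethane = parse_molecule("CC", vocab=vocab)  # no functional groups
        octanol = parse_molecule("CCCCCCCCO", vocab=vocab)  # not in any reaction
        feats = molecule_features_for_property(model, [ethane, octanol])
        d = model.config.dim
        assert feats.shape == (2, 2 * d)
        np.testing.assert_array_equal(feats[0, d:], 0.0)  # zero-count projection
        assert np.any(feats[1, d:] != 0)
        again = molecule_features_for_property(model, [ethane, octanol])
        np.testing.assert_array_equal(feats, again)

    def test_out_of_graph_molecules_counted_as_fallback(self, toy_split, vocab):
        model = _model(toy_split.train, vocab)
        emb = model.embed_reactions(toy_split.test)
        assert emb.n_fallback > 0  # test esters never occur in the train graph


class TestDownstreamHeads:
    def test_reaction_classification_recovers_family_labels(self, small_split, vocab):
        # family labels are highly separable from pair embeddings even
        # with an untrained encoder (functional-group signal)
        from rxgl.training_eval import classify_reactions

        model = _model(small_split.train, vocab, dim=16, seed=0)
        metrics = classify_reactions(
            model, small_split.train, small_split.test, hidden=(32,)
        )
        assert set(metrics) == {"accuracy", "recall_macro", "recall_micro"}
        assert metrics["accuracy"] >= 0.8

    def test_property_prediction_reports_auc(self, small_split, vocab):
        from rxgl.training_eval import predict_property

        model = _model(small_split.train, vocab, dim=16, seed=0)
        # binary property: contains a nitrile (family-1 molecules)
        mols, labels = [], []
        seen = set()
        for rec in small_split.train:
            for m in (*rec.reactants, *rec.products):
                if m.canonical_smiles not in seen:
                    seen.add(m.canonical_smiles)
                    mols.append(m)
                    labels.append(int("C#N" in m.canonical_smiles or "N#C" in m.canonical_smiles))
        labels = np.array(labels)
        # interleave to keep both classes in both halves
        order = np.argsort(labels, kind="stable")
        idx_train = order[::2]
        idx_test = order[1::2]
        out = predict_property(
            model,
            [mols[i] for i in idx_train], labels[idx_train],
            [mols[i] for i in idx_test], labels[idx_test],
        )
        assert 0.5 <= out["auc"] <= 1.0


class TestRelationAnalysis:
    def test_self_pair_has_cosine_one_and_zero_differences(self, toy_records, vocab):
        model = _model(toy_records, vocab)
        rec = toy_records[0]
        analysis = relation_similarity_analysis(model, [rec, rec])
        np.testing.assert_allclose(analysis.cosine, [1.0])
        np.testing.assert_array_equal(analysis.bond_diff, [0.0])
        np.testing.assert_array_equal(analysis.ring_diff, [0.0])

    def test_equal_delta_signatures_give_zero_difference(self, toy_records, vocab):
        model = _model(toy_records, vocab)
        esters = [r for r in toy_records if r.label == 0][:3]
        analysis = relation_similarity_analysis(model, esters)
        np.testing.assert_array_equal(analysis.bond_diff, 0.0)
        np.testing.assert_array_equal(analysis.ring_diff, 0.0)

    def test_binned_summary_covers_all_pairs(self, toy_records, vocab):
        model = _model(toy_records, vocab)
        analysis = relation_similarity_analysis(model, toy_records, n_bins=4)
        n = len(toy_records)
        assert sum(b["n_pairs"] for b in analysis.bins) == n * (n - 1) // 2


class TestPersistence:
    def test_save_load_roundtrip_preserves_scores(self, toy_split, vocab, tmp_path):
        model = _model(toy_split.train, vocab)
        train(model=model, split=toy_split,
              config=TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=0))
        before = rank_products(model, toy_split.test)
        model.save(tmp_path / "model", train_records=toy_split.train)
        loaded = RXGLModel.load(tmp_path / "model")
        after = rank_products(loaded, toy_split.test)
        np.testing.assert_array_equal(before.ranks, after.ranks)
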