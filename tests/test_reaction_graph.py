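"""Reaction-aware graph construction and context-attention encoding."""

import numpy as np

from rxgl.autodiff import Tensor
from rxgl.chemio import parse_reaction_smiles
from rxgl.reaction_graph import (
    ReactionAwareEncoder,
    ReactionEncoderConfig,
    SamplerConfig,
    attention_scores,
    build_reaction_aware_graph,
    draw_neighbor_sample,
    sample_neighbors,
    write_edge_list,
)

# one reactant A giving three products (the star neighborhood motif)
STAR = "CCCCCCO>>CCOC(C)=O.CCCOC(C)=O.CCCCOC(C)=O"


def _graph(lines):
    return build_reaction_aware_graph([parse_reaction_smiles(s) for s in lines])


class TestGraphBuild:
    def test_one_reaction_star(self):
        g = _graph([STAR])
        assert g.num_nodes == 4
        assert len(g.edges) == 3
        a = g.index["CCCCCCO"]
        assert sorted(u for u, v, _ in g.edges) == [a, a, a]

    def test_edge_count_is_cartesian_product_of_sides(self):
        g = _graph(["CCO.CC(=O)O>>CCOC(C)=O.O"])
        assert len(g.edges) == 4  # |R| * |P|

    def test_shared_product_creates_second_order_neighbors(self):
        # A and B both produce F: A-F-B is a path, so A and B are
        # second-order neighbors through the shared product
        g = _graph(["CCCCCO>>CCOC(C)=O", "CCCCCCCO>>CCOC(C)=O"])
        f = g.index["CCOC(C)=O"]
        a, b = g.index["CCCCCO"], g.index["CCCCCCCO"]
        assert {n for n, _ in g.neighbors[f]} == {a, b}
        assert {n for n, _ in g.neighbors[a]} == {f}

    def test_multiple_reactions_keep_one_edge_each(self):
        g = _graph(["CCO>>CC=O", "CCO.O>>CC=O"])  # same pair, two reactions
        pair_edges = [(u, v, r) for u, v, r in g.edges
                      if {u, v} == {g.index["CCO"], g.index["CC=O"]}]
        assert len(pair_edges) == 2
        assert {r for _, _, r in pair_edges} == {0, 1}

    def test_edge_reaction_tags_point_to_opposite_sides(self, small_records):
        g = build_reaction_aware_graph(small_records)
        for u, v, rid in g.edges:
            rec = small_records[rid]
            assert g.molecules[u].canonical_smiles in rec.reactant_smiles
            assert g.molecules[v].canonical_smiles in rec.product_smiles

    def test_build_is_order_invariant(self, small_records):
        g1 = build_reaction_aware_graph(small_records)
        shuffled = [small_records[i]
                    for i in np.random.default_rng(3).permutation(len(small_records))]
        g2 = build_reaction_aware_graph(shuffled)
        def edge_multiset(g, records):
            return sorted(
                (g.molecules[u].canonical_smiles,
                 g.molecules[v].canonical_smiles,
                 records[r].to_reaction_smiles())
                for u, v, r in g.edges
            )
        assert edge_multiset(g1, small_records) == edge_multiset(g2, shuffled)

    def test_edge_list_serialization(self, tmp_path):
        g = _graph([STAR])
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == 3
        assert all(r[0] == "CCCCCCO" and r[2] == "0" for r in rows)


class TestNeighborSampling:
    def test_padding_with_replacement_covers_all(self):
        g = _graph([STAR])
        a = g.index["CCCCCCO"]
        sampled = sample_neighbors(g, a, 10, np.random.default_rng(0))
        assert len(sampled) == 10
        assert {n for n, _ in sampled} == {n for n, _ in g.neighbors[a]}

    def test_large_degree_sampled_without_replacement(self):
        lines = [f"CCCCCCO>>{'C' * i}OC(C)=O" for i in range(1, 16)]
        g = _graph(lines)
        node = g.index["CCCCCCO"]
        assert g.degree(node) > 10
        sampled = sample_neighbors(g, node, 10, np.random.default_rng(0))
        assert len(sampled) == 10
        assert len(set(sampled)) == 10

    def test_deterministic_given_seed(self, small_records):
        g = build_reaction_aware_graph(small_records)
        s1 = draw_neighbor_sample(g, SamplerConfig(Q=10, seed=4))
        s2 = draw_neighbor_sample(g, SamplerConfig(Q=10, seed=4))
        np.testing.assert_array_equal(s1.dst, s2.dst)
        np.testing.assert_array_equal(s1.rid, s2.rid)

    def test_zero_degree_gives_empty_sample(self):
        g = _graph([STAR])
        g.neighbors.append([])  # synthetic isolated node
        assert sample_neighbors(g, g.num_nodes, 5, np.random.default_rng(0)) == []


class TestAttention:
    def test_hand_computed_logits(self):
        # m_i=(1,2), neighbors {(1,0),(0,1)}, c=(1,1), w_a=(1,1):
        # logits (1, 2) -> softmax (e, e^2)/(e + e^2)
        pi = attention_scores(
            Tensor(np.array([1.0, 2.0])),
            Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])),
            Tensor(np.array([1.0, 1.0])),
            Tensor(np.array([1.0, 1.0])),
        )
        e1, e2 = np.e, np.e**2
        np.testing.assert_allclose(pi.data, [e1 / (e1 + e2), e2 / (e1 + e2)])

    def test_identical_neighbors_uniform(self):
        pi = attention_scores(
            Tensor(np.array([1.0, 2.0])),
            Tensor(np.tile([3.0, 4.0], (5, 1))),
            Tensor(np.array([1.0, -1.0])),
            Tensor(np.array([0.3, 0.7])),
        )
        np.testing.assert_allclose(pi.data, 0.2)

    def test_zero_context_uniform(self, rng):
        pi = attention_scores(
            Tensor(rng.standard_normal(4)),
            Tensor(rng.standard_normal((3, 4))),
            Tensor(np.zeros(4)),
            Tensor(rng.standard_normal(4)),
        )
        np.testing.assert_allclose(pi.data, 1 / 3)

    def test_empty_neighborhood_empty_distribution(self):
        pi = attention_scores(
            Tensor(np.ones(2)), Tensor(np.zeros((0, 2))),
            Tensor(np.ones(2)), Tensor(np.ones(2)),
        )
        assert pi.shape == (0,)


class TestEncoding:
    def _encoder(self, d=6, layers=1, seed=0, Q=10):
        return ReactionAwareEncoder(
            ReactionEncoderConfig(num_layers=layers, hidden_dim=d, Q=Q),
            np.random.default_rng(seed),
        )

    def test_attention_normalizes_within_every_node(self, small_records):
        g = build_reaction_aware_graph(small_records)
        enc = self._encoder()
        sample = draw_neighbor_sample(g, SamplerConfig(Q=10, seed=0))
        states = enc.initial_states(g)
        context = Tensor(g.reaction_members @ states.data)
        m_i = states.take_rows(sample.src)
        m_j = states.take_rows(sample.dst)
        c = context.take_rows(sample.rid)
        from rxgl.autodiff import softmax

        logits = ((m_i * m_j * c) @ enc.w_a[0]).reshape(-1, sample.Q)
        pi = softmax(logits, axis=1)
        np.testing.assert_allclose(pi.data.sum(axis=1), 1.0, atol=1e-6)

    def test_isolated_node_keeps_initial_state(self, small_records):
        g = build_reaction_aware_graph(small_records[:3])
        enc = self._encoder()
        sample = draw_neighbor_sample(g, SamplerConfig(Q=4, seed=0))
        # make node 0 isolated by removing its neighbors
        g.neighbors[0] = []
        sample = draw_neighbor_sample(g, SamplerConfig(Q=4, seed=0))
        out = enc.encode(g, sample=sample)
        init = enc.initial_states(g)
        np.testing.assert_allclose(out.data[0], init.data[0])

    def test_single_neighbor_adds_it_fully(self):
        # softmax over one sampled neighbor (all Q draws identical) is 1
        g = _graph(["CCCCCO>>CCOC(C)=O"])
        enc = self._encoder(Q=3)
        sample = draw_neighbor_sample(g, SamplerConfig(Q=3, seed=0))
        out = enc.encode(g, sample=sample).data
        init = enc.initial_states(g).data
        np.testing.assert_allclose(out[0], init[0] + init[1], atol=1e-10)
        np.testing.assert_allclose(out[1], init[1] + init[0], atol=1e-10)

    def test_two_neighbor_hand_expansion(self):
        """One layer on the star graph matches a scalar hand computation."""
        g = _graph([STAR])
        enc = self._encoder(d=3, Q=3)
        sample = draw_neighbor_sample(g, SamplerConfig(Q=3, seed=1))
        out = enc.encode(g, sample=sample).data
        m0 = enc.initial_states(g).data
        w = enc.w_a[0].data
        # context of the single reaction = sum over all four molecules
        c = m0.sum(axis=0)
        a = g.index["CCCCCCO"]
        drawn = [sample.dst[i] for i in range(len(sample.src)) if sample.src[i] == a]
        logits = np.array([w @ (m0[a] * m0[j] * c) for j in drawn])
        pi = np.exp(logits - logits.max())
        pi /= pi.sum()
        expected = m0[a] + sum(p * m0[j] for p, j in zip(pi, drawn))
        np.testing.assert_allclose(out[a], expected, atol=1e-10)

    def test_zero_attention_weight_reduces_to_uniform_mean(self):
        g = _graph([STAR])
        enc = self._encoder(d=4, Q=6)
        enc.w_a[0].data[:] = 0.0
        sample = draw_neighbor_sample(g, SamplerConfig(Q=6, seed=2))
        out = enc.encode(g, sample=sample).data
        m0 = enc.initial_states(g).data
        a = g.index["CCCCCCO"]
        drawn = [sample.dst[i] for i in range(len(sample.src)) if sample.src[i] == a]
        expected = m0[a] + sum(m0[j] for j in drawn) / len(drawn)
        np.testing.assert_allclose(out[a], expected, atol=1e-10)

    def test_fallback_is_projected_fg_vector(self, vocab):
        g = _graph([STAR])
        enc = self._encoder()
        from rxgl.chemio import parse_molecule

        outside = parse_molecule("OCC(O)CO", vocab=vocab)
        fb = enc.fallback_embedding([outside]).data[0]
        np.testing.assert_allclose(
            fb, outside.fg_vector.astype(float) @ enc.fg_embedding.data
        )
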