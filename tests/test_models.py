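import numpy as np
import pytest

from rxnforge import build_cgr, parse_reaction_smiles
from rxnforge.errors import ConfigError, InputError
from rxnforge.models import (DMPNN, GCN, HAN, DimeReaction, FingerprintMLP,
                             ModelConfig, build_model, collate_graphs)
from rxnforge.models.han import _attend, AdditiveAttention
from rxnforge.nn.autodiff import Tensor
from rxnforge.representations import (GeometryPair, ReactionGraph,
                                      Vocabulary, tokenize_smiles)

from .oracles import all_undirected_graphs, dmpnn_edge_states_bruteforce

RNG = np.random.default_rng(42)


def random_graph(edges, n, d_node=4, d_edge=3, rng=RNG):
    src, dst, attr = [], [], []
    for (i, j) in edges:
        feat = rng.normal(size=d_edge)
        src += [i, j]
        dst += [j, i]
        attr += [feat, feat]
    return ReactionGraph(rng.normal(size=(n, d_node)),
                         np.array([src, dst], dtype=int) if src
                         else np.zeros((2, 0), dtype=int),
                         np.array(attr) if attr else np.zeros((0, d_edge)),
                         labels=list(range(1, n + 1)))


class TestMLP:
    def test_zero_weights_output_head_bias(self):
        m = build_model(ModelConfig(architecture="mlp", width=4, depth=2),
                        seed=0, n_bits=8)
        for p in m.parameters():
            p.data[:] = 0.0
        m.net.head.bias.data[:] = 0.7
        out = m(np.zeros((3, 8)))
        assert np.allclose(out.data, 0.7)

    def test_hand_set_weights_match_arithmetic(self):
        m = build_model(ModelConfig(architecture="mlp", width=2, depth=1),
                        seed=0, n_bits=3)
        w1 = np.array([[1.0, -1.0], [0.5, 2.0], [0.0, 1.0]])
        m.net.blocks[0][0].weight.data = w1.copy()
        m.net.blocks[0][0].bias.data = np.array([0.1, -0.2])
        m.net.head.weight.data = np.array([[2.0], [3.0]])
        m.net.head.bias.data = np.array([0.5])
        x = np.array([[1.0, 0.0, 1.0]])
        hidden = np.maximum(x @ w1 + [0.1, -0.2], 0)
        expected = hidden @ [[2.0], [3.0]] + 0.5
        assert np.allclose(m(x).data, expected.ravel())

    def test_eval_mode_deterministic_with_dropout(self):
        m = build_model(ModelConfig(architecture="mlp", width=8, depth=2,
                                    dropout=0.5), seed=1, n_bits=16)
        m.eval()
        x = np.tile(RNG.normal(size=16), (2, 1))
        out = m(x)
        assert out.data[0] == out.data[1]

    def test_parameter_count_analytic(self):
        m = build_model(ModelConfig(architecture="mlp", width=4, depth=2),
                        seed=0, n_bits=8)
        assert m.n_parameters() == (8 * 4 + 4) + (4 * 4 + 4) + (4 * 1 + 1)


class TestDMPNNOracle:
    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_recursion_matches_bruteforce_small_graphs(self, depth):
        model = build_model(ModelConfig(architecture="dmpnn", width=5,
                                        depth=depth), seed=3, d_node=4, d_edge=3)
        w_in = model.w_in.weight.data
        b_in = model.w_in.bias.data
        w_h = model.w_h.weight.data
        for n in (2, 3, 4):
            for edges in all_undirected_graphs(n):
                if not edges:
                    continue
                g = random_graph(edges, n)
                batch = collate_graphs([g])
                h = model.edge_states(batch).data
                directed = list(zip(batch.src.tolist(), batch.dst.tolist()))
                oracle = dmpnn_edge_states_bruteforce(
                    batch.node_x, directed, batch.edge_attr, w_in, b_in, w_h, depth)
                for e, (v, w) in enumerate(directed):
                    assert np.allclose(h[e], oracle[(v, w)], atol=1e-10)

    def test_reverse_edge_excluded(self):
        """On a single bond, the state of a->b after one step gets no message
        (its only incoming edge is its own reverse)."""
        model = build_model(ModelConfig(architecture="dmpnn", width=5, depth=1),
                            seed=0, d_node=4, d_edge=3)
        g = random_graph([(0, 1)], 2)
        batch = collate_graphs([g])
        h1 = model.edge_states(batch).data
        model.cfg.depth = 0
        h0 = model.edge_states(batch).data
        # h1 = relu(h0 + W_h @ 0) = relu(h0) = h0 since h0 >= 0
        assert np.allclose(h1, h0)

    def test_depth0_prediction_uses_only_initial_states(self):
        model = build_model(ModelConfig(architecture="dmpnn", width=4, depth=0),
                            seed=1, d_node=4, d_edge=3)
        g = random_graph([(0, 1), (1, 2)], 3)
        out = model([g])
        assert out.data.shape == (1,) and np.isfinite(out.data).all()

    def test_zero_node_graph_rejected(self):
        empty = ReactionGraph(np.zeros((0, 4)), np.zeros((2, 0), int),
                              np.zeros((0, 3)))
        with pytest.raises(InputError):
            collate_graphs([empty])


class TestGCN:
    def test_single_node_identity_layers_reduce_to_encoder_head(self):
        """With no edges and identity self-maps, extra depth is a no-op:
        the output equals head(encoder(x))."""
        g = random_graph([], 1)
        m = build_model(ModelConfig(architecture="gcn", width=4, depth=4),
                        seed=9, d_node=4, d_edge=3)
        for w_self in m.w_self:
            w_self.weight.data = np.eye(4)
            w_self.bias.data[:] = 0.0
        out = m([g]).data[0]
        h = np.maximum(g.node_features @ m.encoder.weight.data
                       + m.encoder.bias.data, 0.0)
        expected = m.head(Tensor(h)).data[0, 0]
        assert np.allclose(out, expected)

    def test_star_graph_hand_computed(self):
        n, w = 4, 4
        g = random_graph([(0, 1), (0, 2), (0, 3)], n, d_node=w)
        m = build_model(ModelConfig(architecture="gcn", width=w, depth=1,
                                    head_depth=0, activation="identity"),
                        seed=0, d_node=w, d_edge=3)
        m.encoder.weight.data = np.eye(w)
        m.encoder.bias.data[:] = 0.0
        m.w_self[0].weight.data = np.eye(w)
        m.w_self[0].bias.data[:] = 0.0
        m.w_nbr[0].weight.data = np.eye(w)
        m.head.head.weight.data = np.ones((w, 1))
        m.head.head.bias.data[:] = 0.0
        x = g.node_features
        deg = np.array([3.0, 1.0, 1.0, 1.0])
        h = x.copy()
        agg = np.zeros_like(h)
        for (i, j) in [(0, 1), (0, 2), (0, 3)]:
            agg[j] += h[i] / np.sqrt(deg[i] * deg[j])
            agg[i] += h[j] / np.sqrt(deg[i] * deg[j])
        expected = (h + agg).sum()
        assert np.allclose(m([g]).data[0], expected)


class TestGraphPermutationInvariance:
    @pytest.mark.parametrize("arch", ["dmpnn", "gcn"])
    def test_relabeled_reaction_same_prediction(self, arch):
        a = build_cgr(parse_reaction_smiles(
            "[CH3:1][Br:2].[OH-:3]>>[CH3:1][OH:3].[Br-:2]"))
        b = build_cgr(parse_reaction_smiles(
            "[CH3:3][Br:2].[OH-:1]>>[CH3:3][OH:1].[Br-:2]"))
        m = build_model(ModelConfig(architecture=arch, width=8, depth=2),
                        seed=5, d_node=a.node_features.shape[1],
                        d_edge=a.edge_features.shape[1])
        m.eval()
        assert np.allclose(m([a]).data, m([b]).data, rtol=1e-9)


class TestHAN:
    def _model(self, vocab, **kw):
        cfg = ModelConfig(architecture="han", width=6, embedding_dim=6, **kw)
        return build_model(cfg, seed=2, vocab_size=vocab.size)

    def test_attention_weights_sum_to_one(self):
        att = AdditiveAttention(4, np.random.default_rng(0))
        states = [Tensor(RNG.normal(size=(3, 4))) for _ in range(5)]
        mask = np.ones((3, 5))
        mask[1, 3:] = 0
        pooled = _attend(states, mask, att)
        assert pooled.shape == (3, 4)

    def test_single_token_attention_is_identity(self):
        att = AdditiveAttention(4, np.random.default_rng(0))
        s = Tensor(RNG.normal(size=(2, 4)))
        pooled = _attend([s], np.ones((2, 1)), att)
        assert np.allclose(pooled.data, s.data)

    def test_molecule_order_invariance_without_sequence_encoder(self):
        vocab = Vocabulary().fit([tokenize_smiles("CC.O>>CO")])
        m = self._model(vocab, molecule_encoder="none")
        m.eval()
        a = vocab.encode(tokenize_smiles("CC.O>>CO"))
        b = vocab.encode(tokenize_smiles("O.CC>>CO"))
        assert np.allclose(m([a]).data, m([b]).data, rtol=1e-9)

    def test_empty_sequence_rejected(self):
        vocab = Vocabulary().fit([tokenize_smiles("CC")])
        m = self._model(vocab)
        seq = vocab.encode(tokenize_smiles("CC"))
        seq.tokens = []
        with pytest.raises(InputError):
            m([seq])


class TestDimeReaction:
    def _pairs(self):
        coords = RNG.normal(scale=1.2, size=(4, 3))
        other = RNG.normal(scale=1.2, size=(4, 3))
        return (GeometryPair(["C", "O", "N", "C"], coords, coords),
                GeometryPair(["C", "O", "N", "C"], other, other))

    def _model(self, **kw):
        cfg = ModelConfig(architecture="dimereaction", width=8, n_blocks=2,
                          cutoff=5.0, pooling="mean", **kw)
        return build_model(cfg, seed=7)

    def test_identical_pair_collapses_to_head_of_zero(self):
        m = self._model()
        m.eval()
        out = m(list(self._pairs()))
        assert np.allclose(out.data[0], out.data[1], atol=1e-12)

    def test_rigid_motion_invariance(self):
        m = self._model()
        m.eval()
        r = RNG.normal(scale=1.2, size=(5, 3))
        ts = r + RNG.normal(scale=0.1, size=(5, 3))
        elements = ["C", "O", "N", "C", "O"]
        base = m([GeometryPair(elements, r, ts)]).data
        q, _ = np.linalg.qr(RNG.normal(size=(3, 3)))
        shift = np.array([3.0, -2.0, 1.0])
        moved = m([GeometryPair(elements, r @ q.T + shift, ts @ q.T + shift)]).data
        assert np.allclose(base, moved, rtol=1e-5)

    def test_distance_sensitivity(self):
        m = self._model()
        m.eval()
        def pair(d):
            c = np.array([[0.0, 0, 0], [d, 0, 0]])
            return GeometryPair(["C", "O"], c, c * 1.1)
        assert not np.allclose(m([pair(1.0)]).data, m([pair(2.0)]).data)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            build_model(ModelConfig(architecture="dimereaction", cutoff=0.0), seed=0)

    def test_isolated_atom_warns_but_runs(self):
        m = self._model()
        c = np.array([[0.0, 0, 0], [1.0, 0, 0], [50.0, 0, 0]])
        with pytest.warns(UserWarning, match="cutoff"):
            out = m([GeometryPair(["C", "O", "N"], c, c)])
        assert np.isfinite(out.data).all()


def test_max_pooling_routes_gradient_to_argmax():
    from rxnforge.models.base import pool_nodes
    x = Tensor(np.array([[1.0, 5.0], [3.0, 2.0], [7.0, 0.0], [2.0, 9.0]]),
               requires_grad=True)
    out = pool_nodes(x, np.array([0, 0, 1, 1]), 2, "max")
    assert np.array_equal(out.data, [[3.0, 5.0], [7.0, 9.0]])
    out.sum().backward()
    assert np.array_equal(x.grad, [[0, 1], [1, 0], [1, 0], [0, 1]])


def test_registry_stub_raises_helpfully():
    with pytest.raises(ConfigError, match="stub"):
        build_model(ModelConfig(architecture="gat"), seed=0, d_node=4, d_edge=3)


def test_unknown_architecture_lists_registry():
    with pytest.raises(ConfigError, match="registered"):
        build_model(ModelConfig(architecture="nope"), seed=0)
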