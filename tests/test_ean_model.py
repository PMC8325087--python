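import math

import numpy as np
import pytest

import emoattn as ea
from emoattn.corpus_io import EmbeddingMatrix, TokenSequence
from emoattn.ean_model import (
    AttentionParams,
    EncodedSequence,
    FusionGate,
    LstmCellParams,
    LstmState,
    attention_pool,
    bilstm_encode,
    build_variant,
    dynamic_fuse,
    forward_ean,
    loss,
    lstm_step,
)


def zero_cell(d: int, u: int) -> LstmCellParams:
    z = np.zeros((u, u + d))
    b = np.zeros(u)
    return LstmCellParams(W_i=z.copy(), W_f=z.copy(), W_c=z.copy(),
                          W_o=z.copy(), b_i=b.copy(), b_f=b.copy(),
                          b_c=b.copy(), b_o=b.copy())


class TestLstmStep:
    def test_zero_weights_zero_state(self):
        cell = zero_cell(d=3, u=2)
        out = lstm_step(np.ones(3), LstmState.zeros(2), cell)
        np.testing.assert_allclose(out.i, 0.5)
        np.testing.assert_allclose(out.f, 0.5)
        np.testing.assert_allclose(out.o, 0.5)
        np.testing.assert_allclose(out.c, 0.0)
        np.testing.assert_allclose(out.h, 0.0)

    def test_zero_weights_nonzero_cell_closed_form(self):
        # all gates 0.5, candidate 0 -> c_t = 0.5 c, h_t = 0.5 tanh(0.5 c)
        cell = zero_cell(d=3, u=2)
        c = np.array([0.4, -1.2])
        out = lstm_step(np.zeros(3), LstmState(h=np.zeros(2), c=c), cell)
        np.testing.assert_allclose(out.c, 0.5 * c)
        np.testing.assert_allclose(out.h, 0.5 * np.tanh(0.5 * c))

    def test_matches_independent_recurrence_oracle(self):
        """3-step sequence equals an independently coded per-step oracle."""
        rng = np.random.default_rng(42)
        d, u = 4, 3
        cell = LstmCellParams.random(rng, d, u, scale=0.4)
        xs = rng.normal(size=(3, d))
        state = LstmState.zeros(u)
        h_prev, c_prev = np.zeros(u), np.zeros(u)
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        for x in xs:
            state = lstm_step(x, state, cell)
            hx = np.concatenate([h_prev, x])
            i = sig(cell.W_i @ hx + cell.b_i)
            f = sig(cell.W_f @ hx + cell.b_f)
            g = np.tanh(cell.W_c @ hx + cell.b_c)
            o = sig(cell.W_o @ hx + cell.b_o)
            c_prev = f * c_prev + i * g
            h_prev = o * np.tanh(c_prev)
            np.testing.assert_allclose(state.h, h_prev, atol=1e-5)
            np.testing.assert_allclose(state.c, c_prev, atol=1e-5)

    def test_gate_ranges_many_random_trials(self):
        """Sigmoid gates stay strictly inside (0,1) for finite inputs."""
        rng = np.random.default_rng(0)
        d, u = 3, 2
        state = LstmState.zeros(u)
        for _ in range(1000):
            cell = LstmCellParams.random(rng, d, u, scale=1.0)
            state = lstm_step(rng.normal(size=d), state, cell)
            for gate in (state.i, state.f, state.o):
                assert np.all(gate > 0) and np.all(gate < 1)

    def test_shape_mismatch_error(self):
        cell = zero_cell(d=3, u=2)
        with pytest.raises(ValueError):
            lstm_step(np.ones(5), LstmState.zeros(2), cell)


def random_embedding(rng, V, d):
    mat = rng.normal(size=(V, d))
    mat[0] = 0.0
    return EmbeddingMatrix(mat, provenance="random")


class TestBilstmEncode:
    def test_single_token_shape(self):
        rng = np.random.default_rng(1)
        emb = random_embedding(rng, 6, 4)
        u = 3
        fwd = LstmCellParams.random(rng, 4, u)
        bwd = LstmCellParams.random(rng, 4, u)
        seq = TokenSequence(tokens=["a"], ids=[2], length=1)
        enc = bilstm_encode(seq, emb, fwd, bwd)
        assert enc.H.shape == (1, 2 * u)
        assert enc.mask.tolist() == [1.0]

    def test_palindrome_symmetry_with_tied_directions(self):
        """On a palindromic input with fwd == bwd parameters, the forward
        outputs read left-to-right equal the backward outputs right-to-left."""
        rng = np.random.default_rng(2)
        emb = random_embedding(rng, 6, 4)
        u = 3
        cell = LstmCellParams.random(rng, 4, u)
        seq = TokenSequence(tokens=["a", "b", "a"], ids=[2, 3, 2], length=3)
        enc = bilstm_encode(seq, emb, cell, cell)
        np.testing.assert_allclose(enc.H[:, :u], enc.H[::-1, u:], atol=1e-12)

    def test_all_pad_gives_zero_context(self):
        rng = np.random.default_rng(3)
        emb = random_embedding(rng, 6, 4)
        u = 3
        fwd = LstmCellParams.random(rng, 4, u)
        bwd = LstmCellParams.random(rng, 4, u)
        seq = TokenSequence(tokens=["<pad>"] * 4, ids=[0] * 4, length=0)
        enc = bilstm_encode(seq, emb, fwd, bwd)
        assert enc.empty
        att = AttentionParams.random(rng, 2 * u, 2 * u)
        out = attention_pool(enc, att)
        np.testing.assert_array_equal(out.context, 0.0)
        np.testing.assert_array_equal(out.weights, 0.0)

    def test_padding_does_not_change_unmasked_rows(self):
        rng = np.random.default_rng(4)
        emb = random_embedding(rng, 6, 4)
        u = 3
        fwd = LstmCellParams.random(rng, 4, u)
        bwd = LstmCellParams.random(rng, 4, u)
        short = TokenSequence(tokens=["a", "b"], ids=[2, 3], length=2)
        padded = TokenSequence(tokens=["a", "b", "<pad>", "<pad>"],
                               ids=[2, 3, 0, 0], length=2)
        e1 = bilstm_encode(short, emb, fwd, bwd)
        e2 = bilstm_encode(padded, emb, fwd, bwd)
        np.testing.assert_allclose(e1.H, e2.H[:2], atol=1e-12)


class TestAttentionPool:
    def _random(self, rng, n, d):
        H = rng.normal(size=(n, d))
        return EncodedSequence(H=H, mask=np.ones(n))

    def test_identical_rows_uniform_weights(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=6)
        enc = EncodedSequence(H=np.tile(row, (4, 1)), mask=np.ones(4))
        params = AttentionParams.random(rng, 6, 6)
        out = attention_pool(enc, params)
        np.testing.assert_allclose(out.weights, 0.25, atol=1e-12)
        np.testing.assert_allclose(out.context, row, atol=1e-12)

    def test_single_position(self):
        rng = np.random.default_rng(6)
        enc = self._random(rng, 1, 6)
        out = attention_pool(enc, AttentionParams.random(rng, 6, 6))
        np.testing.assert_allclose(out.weights, [1.0])
        np.testing.assert_allclose(out.context, enc.H[0])

    def test_matches_brute_force_oracle(self):
        """Equals an independently coded softmax-and-weighted-sum oracle."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            enc = self._random(rng, 4, 6)
            params = AttentionParams.random(rng, 6, 5, scale=0.5)
            out = attention_pool(enc, params)
            scores = np.array([params.q @ np.tanh(params.Wa.T @ h + params.ba)
                               for h in enc.H])
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            ctx = sum(a * h for a, h in zip(alpha, enc.H))
            np.testing.assert_allclose(out.weights, alpha, atol=1e-6)
            np.testing.assert_allclose(out.context, ctx, atol=1e-6)

    def test_normalization_and_hull_invariants(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(2, 8)
            H = rng.normal(size=(n, 4))
            mask = np.ones(n)
            mask[rng.integers(0, n):] = 0.0
            if mask.sum() == 0:
                mask[0] = 1.0
            enc = EncodedSequence(H=H, mask=mask)
            out = attention_pool(enc, AttentionParams.random(rng, 4, 4))
            valid = mask > 0
            assert abs(out.weights.sum() - 1.0) < 1e-6
            assert np.all(out.weights[~valid] == 0.0)
            lo, hi = H[valid].min(axis=0), H[valid].max(axis=0)
            assert np.all(out.context >= lo - 1e-9)
            assert np.all(out.context <= hi + 1e-9)


class TestDynamicFuse:
    def test_midpoint_idempotent(self):
        v = np.array([1.0, -2.0])
        gate = FusionGate(mode="fixed", theta_fixed=0.5)
        h, theta = dynamic_fuse(v, v, gate)
        assert theta == 0.5
        np.testing.assert_allclose(h, v)

    def test_endpoints(self):
        hp, hn = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        h1, _ = dynamic_fuse(hp, hn, FusionGate(mode="fixed", theta_fixed=1.0))
        h0, _ = dynamic_fuse(hp, hn, FusionGate(mode="fixed", theta_fixed=0.0))
        np.testing.assert_allclose(h1, hp)
        np.testing.assert_allclose(h0, hn)

    def test_direct_substitution(self):
        h, theta = dynamic_fuse(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                FusionGate(mode="fixed", theta_fixed=0.3))
        np.testing.assert_allclose(h, [0.3, 0.7])

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            dynamic_fuse(np.zeros(2), np.zeros(3), FusionGate(mode="fixed"))

    def test_convexity_over_random_gates(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            hp, hn = rng.normal(size=4), rng.normal(size=4)
            gate = FusionGate(mode="per_example",
                              v=rng.normal(size=8), b0=float(rng.normal()))
            h, theta = dynamic_fuse(hp, hn, gate)
            assert 0.0 <= theta <= 1.0
            lo, hi = np.minimum(hp, hn), np.maximum(hp, hn)
            assert np.all(h >= lo - 1e-12) and np.all(h <= hi + 1e-12)


class TestLoss:
    @pytest.mark.parametrize("y,label,expected", [
        ([1.0, 0.0], 0, 0.0),
        ([0.5, 0.5], 0, math.log(2)),
        ([0.5, 0.5], 1, math.log(2)),
        ([0.9, 0.1], 1, -math.log(0.1)),
    ])
    def test_closed_forms(self, y, label, expected):
        assert loss(np.array(y), label) == pytest.approx(expected, abs=1e-9)

    def test_zero_probability_clamped(self):
        val = loss(np.array([1.0, 0.0]), 1)
        assert val == pytest.approx(-math.log(1e-12))


class TestForwardEan:
    def _encoded(self, model, post):
        seq = ea.encode_and_pad(post.text, model.vocab, model.config.max_len)
        split = ea.split_by_polarity(ea.tokenize(post.text), model.lexicon)
        pair = ea.encode_split(split, model.vocab, model.config.max_len_emo)
        return seq, pair

    def test_probabilities_normalized(self, tiny_model_factory, tiny_corpus):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        seq, pair = self._encoded(model, posts[0])
        y, diag = forward_ean(seq, pair, model)
        assert y.shape == (2,)
        assert np.all(y >= 0) and abs(y.sum() - 1.0) < 1e-6
        assert 0.0 <= diag["theta"] <= 1.0

    def test_zero_classifier_uniform(self, tiny_model_factory, tiny_corpus):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        model.params["W"][:] = 0.0
        model.params["b"][:] = 0.0
        seq, pair = self._encoded(model, posts[0])
        y, _ = forward_ean(seq, pair, model)
        np.testing.assert_allclose(y, [0.5, 0.5], atol=1e-12)

    def test_composition_of_verified_sub_operations(self, tiny_model_factory,
                                                    tiny_corpus):
        """The full forward equals the explicit composition of the op-level
        functions (embedding -> Bi-LSTM -> attention -> fusion -> softmax)."""
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        post = posts[1]
        seq, (pos_seq, neg_seq) = self._encoded(model, post)
        y, diag = forward_ean(seq, (pos_seq, neg_seq), model)

        emb = EmbeddingMatrix(model.params["E"], provenance="random")
        u = model.config.hidden_size

        def cell(prefix):
            Wx = model.params[f"{prefix}.Wx"]
            Wh = model.params[f"{prefix}.Wh"]
            b = model.params[f"{prefix}.b"]
            rows = np.concatenate([Wh, Wx], axis=0).T   # (4u, u+d)
            return LstmCellParams(
                W_i=rows[:u], W_f=rows[u:2 * u], W_c=rows[2 * u:3 * u],
                W_o=rows[3 * u:], b_i=b[:u], b_f=b[u:2 * u],
                b_c=b[2 * u:3 * u], b_o=b[3 * u:])

        def att(prefix):
            return AttentionParams(Wa=model.params[f"{prefix}.Wa"],
                                   ba=model.params[f"{prefix}.ba"],
                                   q=model.params[f"{prefix}.q"])

        h_att = attention_pool(
            bilstm_encode(seq, emb, cell("sun_f"), cell("sun_b")),
            att("sun_att")).context
        h_pos = attention_pool(
            bilstm_encode(pos_seq, emb, cell("pos_f"), cell("pos_b")),
            att("pos_att")).context
        h_neg = attention_pool(
            bilstm_encode(neg_seq, emb, cell("neg_f"), cell("neg_b")),
            att("neg_att")).context
        gate = FusionGate(mode="per_example", v=model.params["fuse.v"],
                          b0=float(model.params["fuse.b0"][0]))
        h_emo, theta = dynamic_fuse(h_pos, h_neg, gate)
        f_final = np.concatenate([h_att, h_emo])
        logits = f_final @ model.params["W"] + model.params["b"]
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()

        np.testing.assert_allclose(y, expect, atol=1e-10)
        assert diag["theta"] == pytest.approx(theta, abs=1e-10)


class TestBuildVariant:
    def test_unknown_name_lists_valid(self, tiny_vocab, tiny_corpus):
        _, lexicon = tiny_corpus
        with pytest.raises(ValueError, match="EAN_fixed_fusion"):
            build_variant("bogus", vocab=tiny_vocab, lexicon=lexicon)

    def test_fixed_fusion_theta_half(self, tiny_model_factory, tiny_corpus):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN_fixed_fusion")
        batch = model.encode_posts(posts[:6])
        _, diag = model.forward(batch)
        np.testing.assert_array_equal(diag["theta"], 0.5)

    @pytest.mark.parametrize("variant,factor", [
        ("SUN", 2), ("EUN", 2), ("BiLSTM", 2), ("BiLSTM+Att", 2),
        ("EAN", 4), ("EAN_fixed_fusion", 4), ("SUN+positive", 4),
        ("SUN+negative", 4), ("EAN_concat_fusion", 6),
    ])
    def test_feature_sizes(self, tiny_model_factory, variant, factor):
        model = tiny_model_factory(variant)
        assert model.feature_size == factor * model.config.hidden_size

    def test_lstm_baseline_feature_size(self, tiny_model_factory):
        model = tiny_model_factory("LSTM", hidden_size=6)
        assert model.feature_size == 6

    def test_lstm_baseline_default_units(self, tiny_vocab, tiny_corpus):
        _, lexicon = tiny_corpus
        model = build_variant("LSTM", vocab=tiny_vocab, lexicon=lexicon)
        assert model.config.hidden_size == 128
        model = build_variant("BiLSTM", vocab=tiny_vocab, lexicon=lexicon)
        assert model.config.hidden_size == 64


class TestModelContracts:
    @pytest.mark.parametrize("variant", ["EAN", "SUN", "EUN", "LSTM",
                                         "EAN_concat_fusion"])
    def test_gradients_match_finite_differences(self, tiny_model_factory,
                                                tiny_corpus, gradcheck, variant):
        posts, _ = tiny_corpus
        model = tiny_model_factory(variant)
        batch = model.encode_posts(posts[:6])
        gradcheck(model, batch, n_per_param=3)

    def test_global_fusion_gradients(self, tiny_model_factory, tiny_corpus,
                                     gradcheck):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN", fusion_mode="global")
        batch = model.encode_posts(posts[:6])
        gradcheck(model, batch, n_per_param=3)

    def test_padding_invariance(self, tiny_model_factory, tiny_corpus):
        """Appending PAD tokens never changes the prediction."""
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        batch = model.encode_posts(posts[:4])
        probs, _ = model.forward(batch)
        extra = 5
        wide = dict(batch)
        for key in ("ids", "pos_ids", "neg_ids"):
            arr = batch[key]
            wide[key] = np.concatenate(
                [arr, np.zeros((arr.shape[0], extra), dtype=arr.dtype)], axis=1)
            mkey = key.replace("ids", "mask") if key != "ids" else "mask"
            m = batch[mkey]
            wide[mkey] = np.concatenate([m, np.zeros((m.shape[0], extra))], axis=1)
        probs2, _ = model.forward(wide)
        np.testing.assert_allclose(probs, probs2, atol=1e-6)

    def test_seeded_determinism(self, tiny_model_factory, tiny_corpus):
        posts, _ = tiny_corpus
        m1 = tiny_model_factory("EAN", seed=11)
        m2 = tiny_model_factory("EAN", seed=11)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        p1 = m1.predict_proba(posts[:5])
        p2 = m2.predict_proba(posts[:5])
        np.testing.assert_array_equal(p1, p2)

    def test_save_load_round_trip(self, tiny_model_factory, tiny_corpus, tmp_path):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        model.save(tmp_path / "m")
        back = ea.EanModel.load(tmp_path / "m")
        np.testing.assert_array_equal(model.predict_proba(posts[:4]),
                                      back.predict_proba(posts[:4]))

    def test_diagnostics_records(self, tiny_model_factory, tiny_corpus, tmp_path):
        posts, _ = tiny_corpus
        model = tiny_model_factory("EAN")
        recs = model.diagnostics(posts[:3])
        assert len(recs) == 3
        for rec in recs:
            assert set(rec) >= {"text", "pred", "y", "theta", "top_words", "label"}
        ea.write_diagnostics(recs, tmp_path / "d.jsonl")
        assert (tmp_path / "d.jsonl").read_text().count("\n") == 3
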