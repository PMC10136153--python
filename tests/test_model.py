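"""Forward-pass, attention, GELU, checkpointing and gradient correctness."""

import numpy as np
import pytest
from scipy.special import erf
from scipy.stats import norm

from scpatch import _autograd as ag
from scpatch._autograd import Tensor
from scpatch.io import ExpressionMatrix, LabelMap
from scpatch.model import (ModelConfig, build_model, encoder_block, forward,
                           forward_logits, gelu, load_checkpoint,
                           multi_head_attention, predict_labels,
                           save_checkpoint)


class TestGelu:
    def test_zero(self):
        assert gelu(0.0) == 0.0

    def test_unit_value_from_normal_cdf(self):
        assert gelu(1.0) == pytest.approx(0.841345, abs=1e-6)

    def test_asymptotics(self):
        assert gelu(10.0) == pytest.approx(10.0, abs=1e-6)
        assert gelu(-10.0) == pytest.approx(0.0, abs=1e-6)

    def test_matches_x_times_cdf_on_grid(self):
        x = np.linspace(-4, 4, 101)
        np.testing.assert_allclose(gelu(x), x * norm.cdf(x), atol=1e-12)

    def test_autograd_gelu_consistent_with_scalar(self):
        x = np.linspace(-3, 3, 25)
        np.testing.assert_allclose(ag.gelu(Tensor(x)).data, gelu(x), atol=1e-12)


class TestAttention:
    def _weights(self, d, rng):
        w = {}
        for n in ("wq", "wk", "wv", "wo"):
            w[n] = Tensor(rng.normal(size=(d, d)), requires_grad=True)
        for n in ("bq", "bk", "bv", "bo"):
            w[n] = Tensor(rng.normal(size=d), requires_grad=True)
        return w

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 6, 8)))
        _, attn = multi_head_attention(x, self._weights(8, rng), n_heads=2,
                                       return_attn=True)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_head_matches_hand_rolled_loop(self):
        """2 tokens, D=2: compare against an explicit QK^T/sqrt(d) softmax V loop."""
        rng = np.random.default_rng(1)
        d = 2
        x = rng.normal(size=(1, 2, d))
        w = self._weights(d, rng)
        out = multi_head_attention(Tensor(x), w, n_heads=1)
        q = x[0] @ w["wq"].data.T + w["bq"].data
        k = x[0] @ w["wk"].data.T + w["bk"].data
        v = x[0] @ w["wv"].data.T + w["bv"].data
        expected = np.empty((2, d))
        for i in range(2):
            scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(2)])
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            expected[i] = sum(a[j] * v[j] for j in range(2))
        expected = expected @ w["wo"].data.T + w["bo"].data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)


class TestEncoderBlock:
    def test_zero_weights_reduce_to_identity(self):
        d, rng = 8, np.random.default_rng(0)
        w = {"ln1.gamma": Tensor(np.ones(d)), "ln1.beta": Tensor(np.zeros(d)),
             "ln2.gamma": Tensor(np.ones(d)), "ln2.beta": Tensor(np.zeros(d))}
        for n in ("wq", "wk", "wv", "wo"):
            w["attn." + n] = Tensor(np.zeros((d, d)))
        for n in ("bq", "bk", "bv", "bo"):
            w["attn." + n] = Tensor(np.zeros(d))
        w["mlp.w1"] = Tensor(np.zeros((16, d)))
        w["mlp.b1"] = Tensor(np.zeros(16))
        w["mlp.w2"] = Tensor(np.zeros((d, 16)))
        w["mlp.b2"] = Tensor(np.zeros(d))
        h = rng.normal(size=(3, d))
        out = encoder_block(h, w, n_heads=2)
        np.testing.assert_allclose(out.data, h, atol=1e-12)


class TestForward:
    def test_probabilities_sum_to_one(self, small_state):
        rng = np.random.default_rng(0)
        p = forward(rng.normal(size=100) ** 2, small_state)
        assert p.shape == (2,)
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_patch_shuffle_invariance_with_mean_pooling(self):
        """Zero positions + mean pooling: token order cannot matter."""
        lm = LabelMap(["a", "b", "c"])
        cfg = ModelConfig.desk_preset(n_classes=3, patch_size=4, embed_dim=16,
                                      depth=2, n_heads=2, pooling="mean")
        state = build_model(n_genes=64, label_map=lm, config=cfg, seed=0)
        state.params["pos_table"].data[:] = 0.0
        rng = np.random.default_rng(5)
        v = rng.normal(size=64) ** 2
        p_ref = forward(v, state)
        # shuffle whole patches (blocks of P^2 = 16 genes)
        order = rng.permutation(4)
        shuffled = v.reshape(4, 16)[order].reshape(-1)
        p_shuf = forward(shuffled, state)
        np.testing.assert_allclose(p_shuf, p_ref, atol=1e-6)

    def test_inference_reproducible(self, small_state):
        v = np.random.default_rng(1).normal(size=100) ** 2
        np.testing.assert_array_equal(forward(v, small_state),
                                      forward(v, small_state))

    def test_length_mismatch_rejected(self, small_state):
        with pytest.raises(ValueError):
            forward(np.zeros(99), small_state)

    def test_depth_zero_matches_independent_numpy_pipeline(self):
        lm = LabelMap(["a", "b"])
        cfg = ModelConfig.desk_preset(n_classes=2, patch_size=3, embed_dim=8,
                                      depth=0, n_heads=2,
                                      classifier_hidden=(8, 4))
        state = build_model(n_genes=18, label_map=lm, config=cfg, seed=9)
        v = np.random.default_rng(2).normal(size=18) ** 2
        got = forward(v, state)

        p = {k: t.data for k, t in state.params.items()}
        tokens = v.reshape(2, 9) @ p["patch_proj.weight"].T + p["patch_proj.bias"]
        h = np.vstack([p["class_token"], tokens]) + p["pos_table"]
        mu, sd = h.mean(1, keepdims=True), h.std(1, keepdims=True)
        h = p["final_ln.gamma"] * (h - mu) / np.sqrt(sd ** 2 + 1e-6) \
            + p["final_ln.beta"]
        pooled = h[0]
        f = lambda x: x * 0.5 * (1 + erf(x / np.sqrt(2)))
        z = f(pooled @ p["head.w1"].T + p["head.b1"])
        z = f(z @ p["head.w2"].T + p["head.b2"])
        logits = z @ p["head.w3"].T + p["head.b3"]
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestPredictLabels:
    def _aligned_matrix(self, n_cells, n_genes, state):
        rng = np.random.default_rng(0)
        return ExpressionMatrix(rng.normal(size=(n_cells, n_genes)) ** 2,
                                [f"g{i}" for i in range(n_genes)],
                                [f"c{i}" for i in range(n_cells)],
                                normalized=True)

    def test_frozen_head_gives_softmax_closed_form(self, small_state):
        # force constant logits (1, 0) regardless of input
        small_state.params["head.w3"].data[:] = 0.0
        small_state.params["head.b3"].data[:] = np.array([1.0, 0.0])
        m = self._aligned_matrix(4, 100, small_state)
        out = predict_labels(m, small_state)
        e = np.e
        for _, label, conf in out:
            assert label == "alpha"
            assert conf == pytest.approx(e / (e + 1), abs=1e-9)

    def test_empty_matrix_gives_empty_list(self, small_state):
        m = ExpressionMatrix(np.zeros((0, 100)),
                             [f"g{i}" for i in range(100)], [],
                             normalized=True)
        assert predict_labels(m, small_state) == []

    def test_confidence_equals_max_probability(self, small_state):
        m = self._aligned_matrix(3, 100, small_state)
        out = predict_labels(m, small_state)
        for (cid, _, conf), row in zip(out, m.values):
            assert conf == pytest.approx(forward(row, small_state).max())


class TestCheckpoint:
    def test_round_trip_bit_exact_forward(self, small_state, tmp_path):
        v = np.random.default_rng(3).normal(size=100) ** 2
        before = forward(v, small_state)
        save_checkpoint(small_state, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        after = forward(v, loaded)
        np.testing.assert_array_equal(before, after)  # bit-for-float
        for k, t in small_state.params.items():
            np.testing.assert_array_equal(t.data, loaded.params[k].data)
        assert loaded.config == small_state.config
        assert loaded.layout == small_state.layout
        assert loaded.label_map.names == small_state.label_map.names


class TestGradients:
    def test_finite_difference_agreement_on_sampled_parameters(self):
        """Analytic gradients match central differences on a tiny model."""
        lm = LabelMap(["a", "b", "c"])
        cfg = ModelConfig.desk_preset(n_classes=3, patch_size=2, embed_dim=8,
                                      depth=1, n_heads=2,
                                      classifier_hidden=(8, 4),
                                      dropout=0.0, input_dropout=0.0)
        state = build_model(n_genes=12, label_map=lm, config=cfg, seed=0)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 12)) ** 2
        y = np.array([0, 1, 2, 0, 1])

        def loss_value():
            logits = forward_logits(x, state, training=False)
            return ag.cross_entropy_with_logits(logits, y)

        loss = loss_value()
        state.zero_grad()
        loss.backward()

        names = sorted(state.params)
        checked = 0
        eps = 1e-6
        for name in names:
            p = state.params[name]
            flat_idx = rng.integers(p.data.size)
            idx = np.unravel_index(flat_idx, p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            up = float(loss_value().data)
            p.data[idx] = orig - eps
            down = float(loss_value().data)
            p.data[idx] = orig
            fd = (up - down) / (2 * eps)
            an = p.grad[idx]
            if abs(fd) < 1e-10 and abs(an) < 1e-10:
                continue
            assert an == pytest.approx(fd, rel=1e-3, abs=1e-8), name
            checked += 1
            if checked >= 20:
                break
        assert checked >= 20
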