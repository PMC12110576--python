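"""SWT network: shapes, attention oracle, head arithmetic, complexity."""

import numpy as np
import pytest

from mclswt import (
    ModelConfig,
    SWTModel,
    attention_cost,
    load_checkpoint,
    measure_attention_macs,
    partition_windows,
    save_checkpoint,
    windowed_attention,
)
from mclswt.autodiff import Tensor

RNG = np.random.default_rng(7)


def global_masked_attention(x, wq, wk, wv, wo, wo_b, n_heads, mask):
    """Brute-force oracle: full L x L attention under an additive mask.

    Computes softmax(Q K^T / sqrt(dk) + mask) V per head over the whole
    sequence, then concatenates heads and projects. ``mask`` is 0 where
    attention is allowed and -inf elsewhere.
    """
    B, L, D = x.shape
    dh = D // n_heads
    out = np.empty_like(x)
    for b in range(B):
        heads = []
        q, k, v = x[b] @ wq, x[b] @ wk, x[b] @ wv
        for h in range(n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            s = q[:, sl] @ k[:, sl].T / np.sqrt(dh) + mask
            s = s - s.max(axis=1, keepdims=True)
            a = np.exp(s)
            a /= a.sum(axis=1, keepdims=True)
            heads.append(a @ v[:, sl])
        out[b] = np.concatenate(heads, axis=1) @ wo + wo_b
    return out


def block_mask(L, M, shift=0):
    """Additive mask for contiguous windows of a (shifted) partition."""
    groups = (np.arange(L) + shift) % L // M
    allowed = groups[:, None] == groups[None, :]
    return np.where(allowed, 0.0, -np.inf)


class TestPartitionWindows:
    def test_two_windows(self):
        w = partition_windows(np.arange(16), 8)
        assert w.shape == (2, 8)

    def test_1096_over_8(self):
        assert partition_windows(np.zeros((1096, 4)), 8).shape == (137, 8, 4)

    def test_non_divisible_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            partition_windows(np.zeros(10), 8)

    def test_concatenation_reconstructs(self):
        x = RNG.standard_normal((24, 3))
        np.testing.assert_array_equal(partition_windows(x, 8).reshape(24, 3), x)


class TestFeatureExtractor:
    def test_valid_convolution_length(self):
        cfg = ModelConfig(d_model=16, n_heads=4)
        assert cfg.seq_len(1120) == 1096

    def test_too_short_trial_errors(self):
        cfg = ModelConfig()
        with pytest.raises(ValueError, match="kernel"):
            cfg.seq_len(10)

    def test_zero_input_gives_bn_shift_only(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=1)
        beta_val = 0.37
        model.params["bn_beta"].data[:] = beta_val
        x = np.zeros((2, 40, 3))
        f = model._features(Tensor(x), training=False)
        np.testing.assert_allclose(f.data, beta_val, rtol=1e-5)

    def test_channel_axis_collapsed(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=1)
        x = RNG.standard_normal((2, 40, 3))
        f = model._features(Tensor(x), training=True)
        assert f.shape == (2, 36, tiny_model_cfg.d_model)


class TestWindowedAttentionOracle:
    def _weights(self, D):
        ws = {k: Tensor(RNG.standard_normal((D, D)) / np.sqrt(D)) for k in "qkvo"}
        b = Tensor(RNG.standard_normal(D) * 0.1)
        return ws, b

    @pytest.mark.parametrize("shifted", [False, True])
    def test_matches_masked_global_attention(self, shifted):
        L, D, H, M = 32, 8, 2, 8
        ws, b = self._weights(D)
        x = RNG.standard_normal((2, L, D))
        out = windowed_attention(
            Tensor(x), ws["q"], ws["k"], ws["v"], ws["o"], b, H, M, shifted=shifted
        ).data
        mask = block_mask(L, M, shift=M // 2 if shifted else 0)
        oracle = global_masked_attention(
            x, ws["q"].data, ws["k"].data, ws["v"].data, ws["o"].data, b.data, H, mask
        )
        assert np.abs(out - oracle).max() < 1e-5

    def test_identical_tokens_attention_is_projection(self):
        # equal keys -> uniform softmax -> output = projected token value
        L, D, H, M = 16, 8, 2, 8
        ws, b = self._weights(D)
        tok = RNG.standard_normal(D)
        x = np.tile(tok, (1, L, 1))
        out = windowed_attention(Tensor(x), ws["q"], ws["k"], ws["v"], ws["o"], b, H, M).data
        expected = tok @ ws["v"].data @ ws["o"].data + b.data
        np.testing.assert_allclose(out, np.tile(expected, (1, L, 1)), rtol=1e-6, atol=1e-8)

    def test_shift_is_noop_on_identical_tokens(self):
        L, D, H, M = 16, 8, 2, 8
        ws, b = self._weights(D)
        x = np.tile(RNG.standard_normal(D), (1, L, 1))
        args = (Tensor(x), ws["q"], ws["k"], ws["v"], ws["o"], b, H, M)
        np.testing.assert_allclose(
            windowed_attention(*args, shifted=False).data,
            windowed_attention(*args, shifted=True).data,
            rtol=1e-6,
        )

    def test_non_divisible_length_errors(self):
        ws, b = self._weights(8)
        with pytest.raises(ValueError, match="divisible"):
            windowed_attention(Tensor(np.zeros((1, 10, 8))), ws["q"], ws["k"],
                               ws["v"], ws["o"], b, 2, 8)


class TestHead:
    def test_probabilities_normalized(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=2)
        out = model.forward(RNG.standard_normal((5, 40, 3)))
        assert np.all(out.probs.data >= 0)
        np.testing.assert_allclose(out.probs.data.sum(axis=1), 1.0, rtol=1e-6)

    def test_constant_activation_square_log_arithmetic(self, tiny_model_cfg):
        # constant pre-pool activation c -> post-log feature 2 ln c everywhere
        model = SWTModel(tiny_model_cfg, rng=3)
        c = 1.7
        a = Tensor(np.full((1, 36, tiny_model_cfg.d_model), c))
        _, _, emb = model._head(a)
        np.testing.assert_allclose(emb.data, 2.0 * np.log(c), rtol=1e-6)

    def test_embedding_is_pre_fc_vector(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=4)
        out = model.forward(RNG.standard_normal((3, 40, 3)))
        logits = out.embedding.data @ model.params["fc_w"].data + model.params["fc_b"].data
        np.testing.assert_allclose(logits, out.logits.data, rtol=1e-5, atol=1e-8)

    def test_log_floor_guards_zero_input(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=5)
        out = model.forward(np.zeros((1, 40, 3)))
        assert np.all(np.isfinite(out.embedding.data))


class TestModelForward:
    def test_deterministic_and_batch_independent(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=6)
        x = RNG.standard_normal((4, 40, 3))
        single = model.forward(x[:1]).probs.data
        dup = model.forward(np.concatenate([x[:1], x])).probs.data
        np.testing.assert_allclose(dup[0], single[0], rtol=1e-6)
        np.testing.assert_allclose(dup[0], dup[1], rtol=1e-6)

    def test_batch_permutation_permutes_outputs(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=6)
        x = RNG.standard_normal((4, 40, 3))
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(
            model.forward(x[perm]).probs.data, model.forward(x).probs.data[perm], rtol=1e-6
        )

    def test_smoke_finite_on_random_weights(self, tiny_model_cfg):
        model = SWTModel(tiny_model_cfg, rng=7)
        out = model.forward(RNG.standard_normal((8, 40, 3)), training=True)
        assert np.isfinite(out.probs.data).all()
        assert np.isfinite(out.embedding.data).all()

    def test_checkpoint_roundtrip(self, tiny_model_cfg, tmp_path):
        model = SWTModel(tiny_model_cfg, rng=8)
        x = RNG.standard_normal((2, 40, 3))
        before = model.forward(x).probs.data
        save_checkpoint(tmp_path / "ckpt.npz", model)
        model2 = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(model2.forward(x).probs.data, before)


class TestComplexity:
    def test_closed_form_values(self):
        msa, wmsa = attention_cost(1096, 40, 8)
        assert msa == 103_111_680
        assert wmsa == 15_431_680

    def test_window_equal_to_length(self):
        L, D = 64, 16
        msa, wmsa = attention_cost(L, D, L)
        assert wmsa == 8 * L * D**2 + 4 * L**2 * D

    def test_doubling_length_scales_terms(self):
        L, D, M = 128, 16, 8
        _, w1 = attention_cost(L, D, M)
        _, w2 = attention_cost(2 * L, D, M)
        # linear: both terms double exactly
        assert w2 == 2 * w1
        m1 = attention_cost(L, D, M)[0] - 4 * L * D**2
        m2 = attention_cost(2 * L, D, M)[0] - 4 * 2 * L * D**2
        assert m2 == 4 * m1  # quadratic term quadruples

    def test_measured_macs_equal_formula(self):
        L, D, H, M = 256, 16, 4, 8
        assert measure_attention_macs(L, D, H, M) == attention_cost(L, D, M)[1]

    def test_measured_global_macs_quadratic(self):
        # one global block executes exactly 4 L D^2 + 2 L^2 D multiply-adds
        L, D, H = 64, 16, 4
        assert measure_attention_macs(L, D, H, None) == attention_cost(L, D, 8)[0]
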