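"""Network-layer correctness: convolution oracles, LSTM equations, gradients,
causality and multi-scale shape contracts."""

import numpy as np
import pytest

from pcgseg import nn
from pcgseg.tblstm_model import (
    LSTMParams,
    ModelConfig,
    ResidualBlock,
    build_model,
    causal_conv,
    dilated_causal_conv,
    lstm_step,
)


# ---------------------------------------------------------------------------
# Convolution oracles
# ---------------------------------------------------------------------------

def brute_force_dilated_conv(x, f, d):
    """Literal evaluation: y_n = sum_{k=1..K} f_k x_{n-(K-k)d}, zeros outside."""
    K, N = len(f), len(x)
    y = np.zeros(N)
    for n in range(N):
        for k in range(1, K + 1):
            idx = n - (K - k) * d
            if idx >= 0:
                y[n] += f[k - 1] * x[idx]
    return y


class TestConvOracles:
    def test_printed_examples(self):
        np.testing.assert_allclose(causal_conv([1, 2, 3, 4], [1, 1]), [1, 3, 5, 7])
        np.testing.assert_allclose(
            dilated_causal_conv([1, 2, 3, 4], [1, 1], 2), [1, 2, 4, 6]
        )

    def test_k1_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_allclose(causal_conv(x, [1.0]), x)

    def test_d1_reduces_to_causal(self, rng):
        x, f = rng.standard_normal(30), rng.standard_normal(4)
        np.testing.assert_allclose(
            dilated_causal_conv(x, f, 1), causal_conv(x, f), atol=1e-12
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(120):
            N = int(rng.integers(1, 40))
            K = int(rng.integers(1, 6))
            d = int(rng.integers(1, 9))
            x = rng.standard_normal(N)
            f = rng.standard_normal(K)
            np.testing.assert_allclose(
                dilated_causal_conv(x, f, d),
                brute_force_dilated_conv(x, f, d),
                atol=1e-9,
            )

    def test_causality_perturbation(self, rng):
        x = rng.standard_normal(50)
        f = rng.standard_normal(3)
        y = causal_conv(x, f)
        j = 20
        x2 = x.copy()
        x2[j] += 1.0
        y2 = causal_conv(x2, f)
        assert np.allclose(y[:j], y2[:j])
        assert not np.allclose(y[j:], y2[j:])

    @pytest.mark.parametrize("K,d", [(2, 1), (2, 16), (3, 4), (3, 16)])
    def test_receptive_field_by_probing(self, K, d, rng):
        """Impulse response support equals (K-1)*d + 1."""
        layer = nn.CausalConv1d(1, 1, K, d, rng)
        layer.b.data[:] = 0.0
        layer.W.data[:] = 1.0
        T = (K - 1) * d + 20
        x = np.zeros((1, T, 1))
        x[0, 0, 0] = 1.0
        y = layer.forward(x)[0, :, 0]
        nonzero = np.flatnonzero(np.abs(y) > 1e-12)
        assert nonzero.max() == (K - 1) * d  # last influenced frame
        assert layer.receptive_field == (K - 1) * d + 1


# ---------------------------------------------------------------------------
# LSTM equations
# ---------------------------------------------------------------------------

def scalar_lstm_oracle(x_t, h_prev, c_prev, p):
    """Independent element-by-element transcription of the gate equations."""
    H = len(h_prev)
    hx = list(h_prev) + list(x_t)
    out_h, out_c = np.zeros(H), np.zeros(H)
    for j in range(H):
        zi = sum(p.W_i[j][m] * hx[m] for m in range(len(hx))) + p.b_i[j]
        zf = sum(p.W_f[j][m] * hx[m] for m in range(len(hx))) + p.b_f[j]
        zo = sum(p.W_o[j][m] * hx[m] for m in range(len(hx))) + p.b_o[j]
        zc = sum(p.W_C[j][m] * hx[m] for m in range(len(hx))) + p.b_C[j]
        i = 1.0 / (1.0 + np.exp(-zi))
        f = 1.0 / (1.0 + np.exp(-zf))
        o = 1.0 / (1.0 + np.exp(-zo))
        ct = f * c_prev[j] + i * np.tanh(zc)
        out_c[j] = ct
        out_h[j] = o * np.tanh(ct)
    return out_h, out_c


def _random_params(rng, H, C):
    mk = lambda: rng.standard_normal((H, H + C))
    vk = lambda: rng.standard_normal(H)
    return LSTMParams(mk(), mk(), mk(), mk(), vk(), vk(), vk(), vk())


class TestLSTMStep:
    def test_zero_weights_half_gates(self):
        H, C = 3, 2
        z = np.zeros
        p = LSTMParams(*(z((H, H + C)) for _ in range(4)), *(z(H) for _ in range(4)))
        c_prev = np.array([0.4, -0.2, 1.0])
        h, c = lstm_step(np.ones(C), np.zeros(H), c_prev, p)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_output_bounded(self, rng):
        p = _random_params(rng, 4, 3)
        h, _ = lstm_step(10 * rng.standard_normal(3), rng.standard_normal(4),
                         10 * rng.standard_normal(4), p)
        assert np.all(np.abs(h) < 1.0)

    def test_matches_scalar_oracle_on_random_instances(self, rng):
        for _ in range(100):
            H = int(rng.integers(1, 5))
            C = int(rng.integers(1, 5))
            p = _random_params(rng, H, C)
            x = rng.standard_normal(C)
            h0 = rng.standard_normal(H)
            c0 = rng.standard_normal(H)
            h, c = lstm_step(x, h0, c0, p)
            h_ref, c_ref = scalar_lstm_oracle(x, h0, c0, p)
            np.testing.assert_allclose(h, h_ref, atol=1e-10)
            np.testing.assert_allclose(c, c_ref, atol=1e-10)


class TestBiLSTM:
    def test_palindrome_symmetry_with_shared_weights(self, rng):
        layer = nn.BiLSTM(2, 3, rng, bidirectional=True)
        # share weights between directions
        for pf, pb in zip(layer.fwd.params(), layer.bwd.params()):
            pb.data[...] = pf.data
        half = rng.standard_normal((1, 5, 2))
        x = np.concatenate([half, half[:, ::-1, :]], axis=1)  # palindrome
        out = layer.forward(x)
        H = 3
        np.testing.assert_allclose(out[0, :, :H], out[0, ::-1, H:], atol=1e-12)

    def test_single_frame(self, rng):
        layer = nn.BiLSTM(2, 3, rng)
        x = rng.standard_normal((1, 1, 2))
        out = layer.forward(x)
        hf = layer.fwd.forward(x)
        hb = layer.bwd.forward(x)
        np.testing.assert_allclose(out, np.concatenate([hf, hb], axis=2))

    def test_unidirectional_width(self, rng):
        layer = nn.BiLSTM(2, 5, rng, bidirectional=False)
        out = layer.forward(rng.standard_normal((1, 7, 2)))
        assert out.shape == (1, 7, 5)


# ---------------------------------------------------------------------------
# Gradient checks (finite differences)
# ---------------------------------------------------------------------------

def _num_grad(fun, arr, idx, eps=1e-6):
    old = arr[idx]
    arr[idx] = old + eps
    lp = fun()
    arr[idx] = old - eps
    lm = fun()
    arr[idx] = old
    return (lp - lm) / (2 * eps)


@pytest.mark.parametrize("layer_name", ["conv", "lstm", "bilstm", "block"])
def test_parameter_gradients_match_finite_differences(layer_name, rng):
    x = rng.standard_normal((2, 12, 3))
    if layer_name == "conv":
        layer = nn.CausalConv1d(3, 2, 3, 2, rng)
    elif layer_name == "lstm":
        layer = nn.LSTM(3, 4, rng)
    elif layer_name == "bilstm":
        layer = nn.BiLSTM(3, 4, rng)
    else:
        layer = ResidualBlock(3, 5, 3, 4, rng)
    g_out = rng.standard_normal(layer.forward(x).shape)

    def loss():
        return float(np.sum(layer.forward(x) * g_out))

    for p in layer.params():
        p.zero_grad()
    layer.forward(x)
    dx = layer.backward(g_out)
    for p in layer.params():
        flat, gflat = p.data.reshape(-1), p.grad.reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            num = _num_grad(loss, flat, idx)
            assert abs(num - gflat[idx]) < 1e-5 * max(1.0, abs(num))
    i, j, k = 1, 5, 0
    num = _num_grad(loss, x, (i, j, k))
    assert abs(num - dx[i, j, k]) < 1e-5 * max(1.0, abs(num))


def test_skip_path_carries_gradient_with_zeroed_convs(rng):
    block = ResidualBlock(3, 3, 3, 2, rng)
    block.dconv.W.data[:] = 0.0
    block.dconv.b.data[:] = 0.0
    block.conv.W.data[:] = 0.0
    block.conv.b.data[:] = 0.0
    x = rng.standard_normal((1, 10, 3))
    out = block.forward(x)
    np.testing.assert_allclose(out, x)  # identity through the skip
    g = np.ones_like(out)
    dx = block.backward(g)
    assert np.all(np.abs(dx) > 0)  # gradient flows through the skip


# ---------------------------------------------------------------------------
# Pooling / fusion / full model contracts
# ---------------------------------------------------------------------------

def test_maxpool_definition():
    pool = nn.MaxPool1d()
    x = np.array([3, 1, 4, 1, 5, 9], dtype=float).reshape(1, 6, 1)
    np.testing.assert_allclose(pool.forward(x)[0, :, 0], [3, 4, 9])


def test_maxpool_gradient_routing(rng):
    pool = nn.MaxPool1d()
    x = rng.standard_normal((2, 9, 3))
    y = pool.forward(x)
    g = rng.standard_normal(y.shape)
    dx = pool.backward(g)

    def loss():
        return float(np.sum(pool.forward(x) * g))

    for idx in [(0, 2, 1), (1, 7, 0), (0, 8, 2)]:
        num = _num_grad(loss, x, idx)
        assert abs(num - dx[idx]) < 1e-6


def test_upsample_gradient(rng):
    up = nn.Upsample1d()
    x = rng.standard_normal((1, 7, 2))
    y = up.forward(x, 20)
    g = rng.standard_normal(y.shape)
    dx = up.backward(g)

    def loss():
        return float(np.sum(up.forward(x, 20) * g))

    for idx in [(0, 0, 0), (0, 3, 1), (0, 6, 0)]:
        num = _num_grad(loss, x, idx)
        assert abs(num - dx[idx]) < 1e-6


def _tiny_model(**kw):
    defaults = dict(channels=4, lstm_hidden=4, dropout_rate=0.0, seed=0)
    defaults.update(kw)
    return build_model(ModelConfig(**defaults))


class TestMultiScale:
    def test_internal_lengths_and_fused_shape(self):
        model = _tiny_model()
        x = np.zeros((1, 250, 4))
        fused = model.fuse(x)
        assert fused.shape == (1, 250, 4 * 5)
        lengths = [u._cache[0][1] for u in model.upsamplers]
        assert lengths == [250, 125, 62, 31, 15]  # pre-pool lengths per block

    @pytest.mark.parametrize("T", [32, 33, 100, 4096])
    def test_frame_count_preserved(self, T):
        model = _tiny_model()
        fused = model.fuse(np.zeros((1, T, 4)))
        assert fused.shape[1] == T

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            _tiny_model().fuse(np.zeros((1, 16, 4)))

    def test_sum_fusion_width(self):
        model = _tiny_model(fusion="sum")
        fused = model.fuse(np.zeros((1, 64, 4)))
        assert fused.shape == (1, 64, 4)

    def test_network_causality_of_tcn_stack(self, rng):
        """TCN fusion at frame t must ignore input frames > t."""
        model = _tiny_model()
        x = rng.standard_normal((1, 64, 4))
        base = model.fuse(x.copy())
        x2 = x.copy()
        t_perturb = 40
        x2[0, t_perturb:, :] += rng.standard_normal((64 - t_perturb, 4))
        out2 = model.fuse(x2)
        # pooling halves resolution; frames strictly before the perturbation
        # at the coarsest scale remain identical after upsampling up to the
        # interpolation support around the change point
        safe = t_perturb - 2 ** len(model.blocks)
        np.testing.assert_allclose(base[0, :safe, :], out2[0, :safe, :], atol=1e-10)


class TestFullModel:
    def test_posterior_rows_sum_to_one(self, rng):
        from pcgseg.envelopes import FrameFeatureMatrix

        model = _tiny_model()
        feats = FrameFeatureMatrix(rng.standard_normal((80, 4)), 50.0)
        post = model.posterior(feats)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        assert len(post.argmax()) == 80

    def test_dropout_only_in_training(self, rng):
        model = _tiny_model(dropout_rate=0.5)
        x = rng.standard_normal((1, 40, 4))
        a = model.forward(x, train=False)
        b = model.forward(x, train=False)
        np.testing.assert_allclose(a, b)
        c = model.forward(x, train=True, rng=np.random.default_rng(0))
        assert not np.allclose(a, c)

    def test_softmax_cross_entropy_gradient(self, rng):
        loss_fn = nn.SoftmaxCrossEntropy()
        logits = rng.standard_normal((2, 5, 4))
        labels = rng.integers(0, 4, (2, 5))
        loss_fn.forward(logits, labels)
        grad = loss_fn.backward()

        def loss():
            return loss_fn.forward(logits, labels)

        for idx in [(0, 1, 2), (1, 4, 0)]:
            num = _num_grad(loss, logits, idx)
            assert abs(num - grad[idx]) < 1e-6
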