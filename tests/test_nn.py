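"""Engine-level tests: autodiff correctness, layer semantics, optimizer and
scheduler behavior, all against closed-form or brute-force oracles."""
import math

import numpy as np
import pytest

from tckey import nn
from tckey.nn import Tensor, causal_conv1d, cross_entropy, softmax


class TestAutograd:
    def test_numerical_gradient_composite(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((4, 2)), requires_grad=True)

        def loss():
            return (((a @ b).relu() + 0.3) ** 2).mean()

        l = loss()
        l.backward()
        eps = 1e-6
        for p in (a, b):
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + eps
            lp = loss().item()
            p.data[idx] = old - eps
            lm = loss().item()
            p.data[idx] = old
            assert abs((lp - lm) / (2 * eps) - p.grad[idx]) < 1e-6

    def test_broadcast_add_gradient(self):
        a = Tensor(np.ones((2, 3)), requires_grad=True)
        b = Tensor(np.ones(3), requires_grad=True)
        ((a + b) * 2.0).sum().backward()
        np.testing.assert_allclose(a.grad, 2 * np.ones((2, 3)))
        np.testing.assert_allclose(b.grad, 4 * np.ones(3))

    def test_getitem_gradient_scatter(self):
        x = Tensor(np.arange(6.0).reshape(2, 3), requires_grad=True)
        picked = x[np.array([0, 0, 1]), np.array([1, 1, 2])]
        picked.sum().backward()
        expected = np.zeros((2, 3))
        expected[0, 1] = 2.0
        expected[1, 2] = 1.0
        np.testing.assert_allclose(x.grad, expected)

    def test_backward_requires_scalar(self):
        x = Tensor(np.ones(3), requires_grad=True)
        with pytest.raises(ValueError):
            (x * 2).backward()


class TestSoftmaxCE:
    def test_softmax_simplex(self):
        rng = np.random.default_rng(1)
        p = softmax(Tensor(rng.standard_normal((10, 7)) * 20)).data
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_cross_entropy_uniform(self):
        logits = Tensor(np.zeros((4, 26)), requires_grad=True)
        loss = cross_entropy(logits, np.zeros(4, dtype=int))
        assert abs(loss.item() - math.log(26)) < 1e-12

    def test_cross_entropy_gradient_is_softmax_minus_onehot(self):
        rng = np.random.default_rng(2)
        logits = Tensor(rng.standard_normal((5, 3)), requires_grad=True)
        y = np.array([0, 2, 1, 1, 0])
        cross_entropy(logits, y).backward()
        p = softmax(Tensor(logits.data)).data
        onehot = np.eye(3)[y]
        np.testing.assert_allclose(logits.grad, (p - onehot) / 5, atol=1e-12)


class TestCausalConv:
    def test_impulse_response_k2_d2(self):
        # unit impulse, weights [1, 1], no bias -> nonzero only at t0 and t0+2
        x = np.zeros((1, 1, 12))
        t0 = 3
        x[0, 0, t0] = 1.0
        w = np.array([[[1.0, 1.0]]])  # w[o,c,i]; tap i reaches back i*d samples
        y = causal_conv1d(Tensor(x), Tensor(w), dilation=2).data[0, 0]
        nz = np.nonzero(y)[0]
        np.testing.assert_array_equal(nz, [t0, t0 + 2])

    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(0)
        w = Tensor(rng.standard_normal((3, 2, 4)))
        y = causal_conv1d(Tensor(np.zeros((2, 2, 9))), w, dilation=2)
        np.testing.assert_array_equal(y.data, 0.0)

    def test_causality_future_perturbation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 2, 20))
        w = Tensor(rng.standard_normal((3, 2, 3)))
        y0 = causal_conv1d(Tensor(x), w, dilation=2).data
        x2 = x.copy()
        x2[:, :, 10] += 5.0
        y1 = causal_conv1d(Tensor(x2), w, dilation=2).data
        np.testing.assert_array_equal(y0[:, :, :10], y1[:, :, :10])

    def test_length_preserved_stride1(self):
        y = causal_conv1d(Tensor(np.zeros((1, 1, 17))), Tensor(np.zeros((1, 1, 5))), dilation=3)
        assert y.shape == (1, 1, 17)

    def test_stride_output_length_ceil(self):
        y = causal_conv1d(Tensor(np.zeros((1, 1, 10))), Tensor(np.zeros((1, 1, 2))), stride=4)
        assert y.shape[2] == 3  # ceil(10/4)

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 2, 15))
        w = rng.standard_normal((3, 2, 4))
        k, d = 4, 2
        y = causal_conv1d(Tensor(x), Tensor(w), dilation=d).data
        # brute-force sum over taps of the defining equation
        expected = np.zeros((1, 3, 15))
        for o in range(3):
            for t in range(15):
                s = 0.0
                for c in range(2):
                    for i in range(k):
                        ti = t - d * i
                        if ti >= 0:
                            s += w[o, c, i] * x[0, c, ti]
                expected[0, o, t] = s
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_gradcheck(self):
        rng = np.random.default_rng(5)
        x = Tensor(rng.standard_normal((2, 3, 11)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 3)), requires_grad=True)
        b = Tensor(rng.standard_normal(4), requires_grad=True)
        proj = Tensor(rng.standard_normal((2, 4, 6)))

        def loss():
            return (causal_conv1d(x, w, b, dilation=2, stride=2) * proj).sum()

        loss().backward()
        eps = 1e-6
        for p in (x, w, b):
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + eps
            lp = loss().item()
            p.data[idx] = old - eps
            lm = loss().item()
            p.data[idx] = old
            assert abs((lp - lm) / (2 * eps) - p.grad[idx]) < 1e-6


class TestLayers:
    def test_linear_shapes_and_bias(self):
        rng = np.random.default_rng(0)
        lin = nn.Linear(4, 3, rng=rng)
        y = lin(Tensor(np.ones((2, 4))))
        assert y.shape == (2, 3)

    def test_layernorm_normalizes(self):
        rng = np.random.default_rng(1)
        ln = nn.LayerNorm(8)
        y = ln(Tensor(rng.standard_normal((3, 5, 8)) * 4 + 2)).data
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(y.std(axis=-1), 1.0, atol=1e-2)

    def test_batchnorm_train_normalizes_per_channel(self):
        rng = np.random.default_rng(2)
        bn = nn.BatchNorm1d(3)
        x = rng.standard_normal((8, 3, 20)) * 5 + 1
        y = bn(Tensor(x)).data
        np.testing.assert_allclose(y.mean(axis=(0, 2)), 0.0, atol=1e-8)
        np.testing.assert_allclose(y.std(axis=(0, 2)), 1.0, atol=1e-3)

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(3)
        bn = nn.BatchNorm1d(2)
        for _ in range(50):
            bn(Tensor(rng.standard_normal((16, 2, 10)) * 2 + 3))
        bn.eval()
        y = bn(Tensor(np.full((1, 2, 10), 3.0))).data
        assert np.abs(y).max() < 0.5  # mean input maps near 0 under running stats

    def test_dropout_eval_identity(self):
        ref = nn.RngRef(0)
        drop = nn.Dropout(0.5, ref)
        drop.eval()
        x = np.ones((4, 4))
        np.testing.assert_array_equal(drop(Tensor(x)).data, x)

    def test_dropout_train_masks_and_scales(self):
        ref = nn.RngRef(0)
        drop = nn.Dropout(0.5, ref)
        y = drop(Tensor(np.ones((100, 100)))).data
        assert set(np.unique(y)).issubset({0.0, 2.0})
        assert abs(y.mean() - 1.0) < 0.05

    def test_sinusoidal_row0_pattern(self):
        pe = nn.SinusoidalPositionalEncoding(10, 6)
        row0 = pe.pe[0, 0]
        np.testing.assert_allclose(row0, [0, 1, 0, 1, 0, 1], atol=1e-12)

    def test_state_dict_round_trip(self):
        rng = np.random.default_rng(4)
        ref = nn.RngRef(0)
        layer = nn.EncoderLayer(8, 2, 16, 0.0, ref, rng=rng)
        state = layer.state_dict()
        layer2 = nn.EncoderLayer(8, 2, 16, 0.0, nn.RngRef(1), rng=np.random.default_rng(9))
        layer2.load_state_dict(state)
        x = Tensor(np.random.default_rng(5).standard_normal((2, 3, 8)))
        layer.eval(), layer2.eval()
        np.testing.assert_array_equal(layer(x).data, layer2(x).data)


class TestAttention:
    def test_single_timestep_weight_is_one(self):
        rng = np.random.default_rng(0)
        mha = nn.MultiHeadAttention(8, 2, 0.0, nn.RngRef(0), rng=rng)
        mha.eval()
        x = Tensor(rng.standard_normal((1, 1, 8)))
        w = mha.attention_weights(x)
        np.testing.assert_allclose(w, np.ones((1, 2, 1, 1)), atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        mha = nn.MultiHeadAttention(16, 4, 0.0, nn.RngRef(0), rng=rng)
        mha.eval()
        w = mha.attention_weights(Tensor(rng.standard_normal((2, 9, 16))))
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    @staticmethod
    def brute_force_mha(x, mha):
        """Dense-loop scaled dot-product attention oracle."""
        B, T, D = x.shape
        h = mha.n_heads
        dk = D // h
        q = x @ mha.wq.weight.data + mha.wq.bias.data
        k = x @ mha.wk.weight.data + mha.wk.bias.data
        v = x @ mha.wv.weight.data + mha.wv.bias.data
        out = np.zeros((B, T, D))
        for b in range(B):
            heads = []
            for head in range(h):
                sl = slice(head * dk, (head + 1) * dk)
                qs, ks, vs = q[b, :, sl], k[b, :, sl], v[b, :, sl]
                scores = qs @ ks.T / math.sqrt(dk)
                e = np.exp(scores - scores.max(axis=1, keepdims=True))
                attn = e / e.sum(axis=1, keepdims=True)
                heads.append(attn @ vs)
            out[b] = np.concatenate(heads, axis=1)
        return out @ mha.wo.weight.data + mha.wo.bias.data

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(2)
        mha = nn.MultiHeadAttention(8, 2, 0.0, nn.RngRef(0), rng=rng)
        mha.eval()
        x = rng.standard_normal((3, 8, 8))
        got = mha(Tensor(x)).data
        expected = self.brute_force_mha(x, mha)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_two_step_hand_set_qkv(self):
        mha = nn.MultiHeadAttention(2, 1, 0.0, nn.RngRef(0), rng=np.random.default_rng(0))
        mha.eval()
        for lin in (mha.wq, mha.wk, mha.wv):
            lin.weight.data = np.eye(2)
            lin.bias.data = np.zeros(2)
        mha.wo.weight.data = np.eye(2)
        mha.wo.bias.data = np.zeros(2)
        x = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        got = mha(Tensor(x)).data[0]
        s = 1.0 / math.sqrt(2)
        e = np.exp(np.array([[s, 0.0], [0.0, s]]))
        attn = e / e.sum(axis=1, keepdims=True)
        expected = attn @ x[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestEncoderLayer:
    def test_zero_ffn_reduces_to_layernorm(self):
        rng = np.random.default_rng(0)
        layer = nn.EncoderLayer(8, 2, 16, 0.0, nn.RngRef(0), rng=rng)
        layer.eval()
        layer.ffn.fc1.weight.data[...] = 0.0
        layer.ffn.fc1.bias.data[...] = 0.0
        layer.ffn.fc2.weight.data[...] = 0.0
        layer.ffn.fc2.bias.data[...] = 0.0
        x = Tensor(np.random.default_rng(1).standard_normal((2, 4, 8)))
        z1 = layer.norm1(x + layer.mha(x))
        got = layer(x).data
        expected = layer.norm2(z1).data
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_scalar_level_hand_computation(self):
        # one layer on a 2x4 toy input, checked step by step
        rng = np.random.default_rng(3)
        layer = nn.EncoderLayer(4, 1, 6, 0.0, nn.RngRef(0), rng=rng)
        layer.eval()
        x = rng.standard_normal((1, 2, 4))

        def ln(v, w, b, eps=1e-5):
            mu = v.mean(axis=-1, keepdims=True)
            var = ((v - mu) ** 2).mean(axis=-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * w + b

        mh = TestAttention.brute_force_mha(x, layer.mha)
        z1 = ln(x + mh, layer.norm1.weight.data, layer.norm1.bias.data)
        hidden = np.maximum(z1 @ layer.ffn.fc1.weight.data + layer.ffn.fc1.bias.data, 0.0)
        ffn = hidden @ layer.ffn.fc2.weight.data + layer.ffn.fc2.bias.data
        z2 = ln(z1 + ffn, layer.norm2.weight.data, layer.norm2.bias.data)
        np.testing.assert_allclose(layer(Tensor(x)).data, z2, atol=1e-10)

    def test_permutation_equivariance_without_positions(self):
        rng = np.random.default_rng(4)
        layer = nn.EncoderLayer(8, 2, 16, 0.0, nn.RngRef(0), rng=rng)
        layer.eval()
        x = rng.standard_normal((1, 6, 8))
        perm = np.random.default_rng(5).permutation(6)
        y = layer(Tensor(x)).data
        y_perm = layer(Tensor(x[:, perm])).data
        np.testing.assert_allclose(y_perm, y[:, perm], atol=1e-10)


class TestOptim:
    def test_clip_scales_norm_5_to_1(self):
        p = Tensor(np.zeros(4), requires_grad=True)
        p.grad = np.array([3.0, 4.0, 0.0, 0.0])  # norm 5
        pre = nn.clip_grad_norm([p], 1.0)
        assert abs(pre - 5.0) < 1e-12
        np.testing.assert_allclose(p.grad, [0.6, 0.8, 0.0, 0.0])
        assert abs(np.linalg.norm(p.grad) - 1.0) < 1e-12

    def test_clip_noop_below_max(self):
        p = Tensor(np.zeros(2), requires_grad=True)
        p.grad = np.array([0.3, 0.4])
        nn.clip_grad_norm([p], 1.0)
        np.testing.assert_allclose(p.grad, [0.3, 0.4])

    def test_clip_zero_gradients(self):
        p = Tensor(np.zeros(3), requires_grad=True)
        p.grad = np.zeros(3)
        assert nn.clip_grad_norm([p], 1.0) == 0.0
        np.testing.assert_array_equal(p.grad, 0.0)

    def test_clip_nan_raises_with_name(self):
        p = Tensor(np.zeros(2), requires_grad=True)
        p.name = "blocks.0.conv.weight"
        p.grad = np.array([np.nan, 1.0])
        with pytest.raises(FloatingPointError, match="blocks.0.conv.weight"):
            nn.clip_grad_norm([p], 1.0)

    def test_adam_single_step_matches_formula(self):
        p = Tensor(np.array([1.0]), requires_grad=True)
        p.grad = np.array([0.5])
        opt = nn.Adam([p], lr=0.1)
        opt.step()
        # bias-corrected first step moves by lr * g/(|g| + eps) approx lr
        assert abs(p.data[0] - (1.0 - 0.1)) < 1e-6

    def test_plateau_schedule_frozen_metric(self):
        p = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.Adam([p], lr=1.0)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=2)
        lrs = []
        for _ in range(4):
            sched.step(1.0)
            lrs.append(opt.lr)
        assert lrs == [1.0, 1.0, 1.0, 0.5]
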