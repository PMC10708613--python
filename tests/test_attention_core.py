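"""Primitive transformer operators vs independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.special import erf as scipy_erf

from cptseg import engine, nn
from cptseg.attention_core import (ActivationBlock, DDLayer, MLPBlock,
                                   MultiHeadAttention, ParallelViTLayer,
                                   SerialViTLayer, scaled_dot_attention)
from cptseg.engine import Tensor


# ---------------------------------------------------------------------------
# Independent oracles (explicit loops, no engine code)
# ---------------------------------------------------------------------------

def layer_norm_oracle(x, gain, shift, eps=1e-6):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        out[i] = [(v - mu) / math.sqrt(var + eps) for v in row]
    return out * gain + shift


def dd_oracle(x, w, b):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            wx = sum(w[j, k] * x[i, k] for k in range(x.shape[1])) + b[j]
            out[i, j] = wx * x[i, j] + wx
    return out


def attention_oracle(q, k, v, d_k):
    n, m = q.shape[0], k.shape[0]
    scores = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            scores[i, j] = float(q[i] @ k[j]) / math.sqrt(d_k)
    out = np.zeros((n, v.shape[1]))
    for i in range(n):
        e = np.exp(scores[i] - scores[i].max())
        w = e / e.sum()
        out[i] = sum(w[j] * v[j] for j in range(m))
    return out


def mha_oracle(q, k, v, h, w_out, b_out):
    """Concatenation construction computed head by head."""
    d = q.shape[1]
    dk = d // h
    heads = [attention_oracle(q[:, i * dk:(i + 1) * dk],
                              k[:, i * dk:(i + 1) * dk],
                              v[:, i * dk:(i + 1) * dk], dk)
             for i in range(h)]
    return np.concatenate(heads, axis=1) @ w_out.T + b_out


def gelu_oracle(x):
    return 0.5 * x * (1 + scipy_erf(x / math.sqrt(2)))


# ---------------------------------------------------------------------------
# Layer norm
# ---------------------------------------------------------------------------

class TestLayerNorm:
    def test_constant_rows_map_to_zero(self):
        ln = nn.LayerNorm(5)
        out = ln(Tensor(np.full((3, 5), 7.0))).data
        np.testing.assert_allclose(out, 0.0, atol=1e-3)

    def test_invariant_to_per_row_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 6))
        ln = nn.LayerNorm(6)
        a = ln(Tensor(x)).data
        b = ln(Tensor(x + 5.0)).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 4))
        ln = nn.LayerNorm(4)
        ln.gain.data = rng.normal(size=4)
        ln.shift.data = rng.normal(size=4)
        np.testing.assert_allclose(
            ln(Tensor(x)).data,
            layer_norm_oracle(x, ln.gain.data, ln.shift.data), atol=1e-6)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            nn.LayerNorm(4)(Tensor(np.zeros((2, 5))))


# ---------------------------------------------------------------------------
# DD layer
# ---------------------------------------------------------------------------

class TestDDLayer:
    def test_zero_input_gives_zero(self):
        dd = DDLayer(3, np.random.default_rng(0))
        np.testing.assert_allclose(dd(Tensor(np.zeros((2, 3)))).data, 0.0)

    def test_identity_weight_closed_form(self):
        dd = DDLayer(2, np.random.default_rng(0), bias=False)
        dd.linear.weight.data = np.eye(2)
        out = dd(Tensor(np.array([[2.0, -1.0]]))).data
        np.testing.assert_allclose(out, [[6.0, 0.0]])

    def test_matches_loop_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            d = int(rng.integers(1, 6))
            n = int(rng.integers(1, 5))
            dd = DDLayer(d, rng)
            x = rng.normal(size=(n, d))
            np.testing.assert_allclose(
                dd(Tensor(x)).data,
                dd_oracle(x, dd.linear.weight.data, dd.linear.bias.data),
                atol=1e-6)

    def test_non_square_rejected(self):
        dd = DDLayer(3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            dd(Tensor(np.zeros((2, 4))))


# ---------------------------------------------------------------------------
# Scaled dot-product attention
# ---------------------------------------------------------------------------

class TestScaledDotAttention:
    def test_single_token_returns_value(self):
        rng = np.random.default_rng(2)
        q, k, v = (Tensor(rng.normal(size=(1, 4))) for _ in range(3))
        np.testing.assert_allclose(
            scaled_dot_attention(q, k, v, 4).data, v.data, atol=1e-12)

    def test_identical_keys_give_column_mean(self):
        rng = np.random.default_rng(2)
        q = Tensor(rng.normal(size=(3, 4)))
        k = Tensor(np.tile(rng.normal(size=(1, 4)), (5, 1)))
        v = Tensor(rng.normal(size=(5, 4)))
        out = scaled_dot_attention(q, k, v, 4).data
        np.testing.assert_allclose(out, np.tile(v.data.mean(0), (3, 1)),
                                   atol=1e-12)

    def test_matches_brute_force_oracle_on_100_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 6))
            d = int(rng.integers(1, 7))
            q = rng.normal(size=(n, d))
            k = rng.normal(size=(m, d))
            v = rng.normal(size=(m, d))
            out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), d).data
            np.testing.assert_allclose(out, attention_oracle(q, k, v, d),
                                       atol=1e-6)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        scores = engine.softmax(Tensor(rng.normal(size=(5, 7)) * 10)).data
        np.testing.assert_allclose(scores.sum(-1), 1.0, atol=1e-6)

    def test_invalid_dk_rejected(self):
        t = Tensor(np.zeros((2, 4)))
        with pytest.raises(ValueError):
            scaled_dot_attention(t, t, t, 0)


# ---------------------------------------------------------------------------
# Multi-head attention
# ---------------------------------------------------------------------------

class TestMultiHeadAttention:
    def test_single_head_equals_scaled_dot_plus_projection(self):
        rng = np.random.default_rng(4)
        mha = MultiHeadAttention(4, 1, rng, softmax_dropout=0.0,
                                 output_dropout=0.0)
        mha.eval()
        mha.out_proj.weight.data = np.eye(4)
        mha.out_proj.bias.data = np.zeros(4)
        q, k, v = (Tensor(rng.normal(size=(3, 4))) for _ in range(3))
        np.testing.assert_allclose(
            mha(q, k, v).data, scaled_dot_attention(q, k, v, 4).data,
            atol=1e-12)

    def test_matches_head_by_head_oracle_on_100_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            h = int(rng.choice([1, 2, 4]))
            dk = int(rng.integers(1, 4))
            d = h * dk
            n = int(rng.integers(1, 5))
            mha = MultiHeadAttention(d, h, rng, 0.0, 0.0)
            mha.eval()
            q, k, v = (rng.normal(size=(n, d)) for _ in range(3))
            np.testing.assert_allclose(
                mha(Tensor(q), Tensor(k), Tensor(v)).data,
                mha_oracle(q, k, v, h, mha.out_proj.weight.data,
                           mha.out_proj.bias.data), atol=1e-6)

    def test_zero_inputs_zero_output(self):
        mha = MultiHeadAttention(6, 2, np.random.default_rng(0), 0.0, 0.0)
        mha.eval()
        z = Tensor(np.zeros((4, 6)))
        mha.out_proj.bias.data = np.zeros(6)
        np.testing.assert_allclose(mha(z, z, z).data, 0.0)

    def test_query_permutation_permutes_rows(self):
        rng = np.random.default_rng(6)
        mha = MultiHeadAttention(8, 2, rng, 0.0, 0.0)
        mha.eval()
        q = rng.normal(size=(5, 8))
        k = Tensor(rng.normal(size=(5, 8)))
        v = Tensor(rng.normal(size=(5, 8)))
        perm = rng.permutation(5)
        base = mha(Tensor(q), k, v).data
        permuted = mha(Tensor(q[perm]), k, v).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            MultiHeadAttention(7, 2, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# MLP / activation blocks
# ---------------------------------------------------------------------------

class TestFeedForwardBlocks:
    def test_mlp_zero_input_zero_output(self):
        mlp = MLPBlock(4, 8, np.random.default_rng(0))
        # LN of a zero row is zero, GELU(0)=0, biases are zero at init
        np.testing.assert_allclose(mlp(Tensor(np.zeros((2, 4)))).data, 0.0,
                                   atol=1e-12)

    def test_mlp_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        mlp = MLPBlock(2, 3, rng)
        mlp.fc1.bias.data = rng.normal(size=3)
        mlp.fc2.bias.data = rng.normal(size=2)
        x = rng.normal(size=(4, 2))
        h = layer_norm_oracle(x, mlp.norm.gain.data, mlp.norm.shift.data)
        h = h @ mlp.fc1.weight.data.T + mlp.fc1.bias.data
        h = gelu_oracle(h)
        expect = h @ mlp.fc2.weight.data.T + mlp.fc2.bias.data
        np.testing.assert_allclose(mlp(Tensor(x)).data, expect, atol=1e-6)

    def test_mlp_parameter_count_vit_base(self):
        mlp = MLPBlock(768, 3072, np.random.default_rng(0))
        assert mlp.n_parameters() == 768 * 3072 + 3072 + 3072 * 768 + 768 \
            + 2 * 768

    def test_activation_block_constant_rows_to_zero(self):
        blk = ActivationBlock(6)
        np.testing.assert_allclose(
            blk(Tensor(np.full((3, 6), 2.5))).data, 0.0, atol=1e-3)

    def test_activation_block_parameter_count_is_2d(self):
        assert ActivationBlock(768).n_parameters() == 2 * 768

    def test_activation_block_matches_ln_then_exact_gelu(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 8))
        blk = ActivationBlock(8)
        expect = gelu_oracle(layer_norm_oracle(x, blk.norm.gain.data,
                                               blk.norm.shift.data))
        np.testing.assert_allclose(blk(Tensor(x)).data, expect, atol=1e-6)


# ---------------------------------------------------------------------------
# Serial / parallel ViT layers
# ---------------------------------------------------------------------------

def _zero_residuals(layer: SerialViTLayer):
    layer.attn_block.attn.out_proj.weight.data[:] = 0
    layer.attn_block.attn.out_proj.bias.data[:] = 0
    layer.mlp_block.fc2.weight.data[:] = 0
    layer.mlp_block.fc2.bias.data[:] = 0


class TestViTLayers:
    def test_serial_with_zeroed_projections_is_identity(self):
        layer = SerialViTLayer(8, 2, 16, np.random.default_rng(0), dropout=0.0)
        layer.eval()
        _zero_residuals(layer)
        x = np.random.default_rng(1).normal(size=(3, 8))
        np.testing.assert_allclose(layer(Tensor(x)).data, x, atol=1e-12)

    def test_serial_parameter_count_closed_form(self):
        layer = SerialViTLayer(768, 12, 3072, np.random.default_rng(0))
        attn = 4 * (768 * 768 + 768)
        mlp = 768 * 3072 + 3072 + 3072 * 768 + 768
        norms = 2 * 2 * 768
        assert layer.n_parameters() == attn + mlp + norms

    def test_serial_equals_manual_composition(self):
        rng = np.random.default_rng(5)
        layer = SerialViTLayer(6, 2, 12, rng, dropout=0.0)
        layer.eval()
        x = Tensor(rng.normal(size=(4, 6)))
        step1 = x + layer.attn_block(x)
        expect = step1 + layer.mlp_block(step1)
        np.testing.assert_allclose(layer(x).data, expect.data, atol=1e-12)

    def test_parallel_degenerates_to_serial_when_branch_zeroed(self):
        rng = np.random.default_rng(6)
        par = ParallelViTLayer(2, 8, 2, 16, rng, dropout=0.0)
        par.eval()
        for i in (1,):
            par.attn_branches[i].attn.out_proj.weight.data[:] = 0
            par.attn_branches[i].attn.out_proj.bias.data[:] = 0
            par.mlp_branches[i].fc2.weight.data[:] = 0
            par.mlp_branches[i].fc2.bias.data[:] = 0
        ser = SerialViTLayer(8, 2, 16, np.random.default_rng(99), dropout=0.0)
        ser.eval()
        ser.attn_block.load_state_dict(par.attn_branches[0].state_dict())
        ser.mlp_block.load_state_dict(par.mlp_branches[0].state_dict())
        x = np.random.default_rng(7).normal(size=(3, 8))
        np.testing.assert_allclose(ser(Tensor(x)).data, par(Tensor(x)).data,
                                   atol=1e-12)

    def test_parallel_equals_explicit_three_branch_sum(self):
        rng = np.random.default_rng(6)
        par = ParallelViTLayer(3, 6, 2, 12, rng, dropout=0.0)
        par.eval()
        x = Tensor(rng.normal(size=(4, 6)))
        s = x
        for b in par.attn_branches:
            s = s + b(x)
        expect = s
        for b in par.mlp_branches:
            expect = expect + b(s)
        np.testing.assert_allclose(par(x).data, expect.data, atol=1e-12)

    def test_parallel_param_total_depends_only_on_depth_times_branches(self):
        rng = np.random.default_rng(0)
        def total(layers, branches):
            return sum(
                ParallelViTLayer(branches, 8, 2, 16, rng).n_parameters()
                for _ in range(layers))
        assert total(6, 2) == total(4, 3) == total(3, 4) == \
            sum(SerialViTLayer(8, 2, 16, rng).n_parameters()
                for _ in range(12))

    def test_single_branch_rejected(self):
        with pytest.raises(ValueError):
            ParallelViTLayer(1, 8, 2, 16, np.random.default_rng(0))


def test_eval_mode_forwards_are_bitwise_deterministic():
    rng = np.random.default_rng(8)
    layer = SerialViTLayer(8, 2, 16, rng, dropout=0.2)
    layer.eval()
    x = Tensor(rng.normal(size=(5, 8)))
    a = layer(x).data
    b = layer(x).data
    assert np.array_equal(a, b)


def test_train_mode_dropout_reproducible_under_seed():
    def run():
        layer = SerialViTLayer(8, 2, 16, np.random.default_rng(9), dropout=0.3)
        layer.train()
        return layer(Tensor(np.ones((5, 8)))).data
    assert np.array_equal(run(), run())
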