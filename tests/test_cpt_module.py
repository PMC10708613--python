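"""Cross-parallel transformer block: composition oracles and wiring."""

import numpy as np
import pytest

from cptseg.cpt_module import (CPMHSA, CPTConfig, CPTLayer, CrossPair,
                               build_cpt_stack)
from cptseg.engine import Tensor

SMALL = dict(hidden_dim=8, heads=2, mlp_dim=16, dropout=0.0)


def small_cfg(**kw):
    base = dict(depth=1, parallelism=2, dd_layers=1, mlp_layers=0, **SMALL)
    base.update(kw)
    return CPTConfig(**base)


def make_pair(seed=0, **kw) -> CrossPair:
    pair = CrossPair(small_cfg(**kw), np.random.default_rng(seed))
    pair.eval()
    return pair


class TestBranchProject:
    def test_constant_rows_give_broadcast_biases(self):
        pair = make_pair(7)
        q, k, v = pair.left.project(Tensor(np.full((3, 8), 4.0)))
        for t, lin in ((q, pair.left.q_proj), (k, pair.left.k_proj),
                       (v, pair.left.v_proj)):
            np.testing.assert_allclose(t.data, np.tile(lin.bias.data, (3, 1)),
                                       atol=1e-3)

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(7)
        pair = make_pair(7)
        x = rng.normal(size=(4, 8))
        a = pair.left.project(Tensor(x))
        b = pair.left.project(Tensor(x + 3.0))
        for t1, t2 in zip(a, b):
            np.testing.assert_allclose(t1.data, t2.data, atol=1e-9)

    def test_matches_layernorm_linear_composition(self):
        rng = np.random.default_rng(7)
        pair = make_pair(7)
        x = rng.normal(size=(5, 8))
        h = pair.left.norm_in(Tensor(x))
        q, k, v = pair.left.project(Tensor(x))
        np.testing.assert_allclose(q.data, pair.left.q_proj(h).data, atol=1e-12)
        np.testing.assert_allclose(k.data, pair.left.k_proj(h).data, atol=1e-12)
        np.testing.assert_allclose(v.data, pair.left.v_proj(h).data, atol=1e-12)


class TestDDStack:
    def test_zero_layers_is_identity(self):
        pair = make_pair(8, dd_layers=0)
        x = Tensor(np.random.default_rng(8).normal(size=(3, 8)))
        q, k, v = pair.left.apply_dd_stack(x, x, x)
        for t in (q, k, v):
            assert t is x

    def test_zero_input_stays_zero(self):
        pair = make_pair(8, dd_layers=1)
        z = Tensor(np.zeros((2, 8)))
        q, _, _ = pair.left.apply_dd_stack(z, z, z)
        np.testing.assert_allclose(q.data, 0.0)

    def test_two_layers_equal_nested_application(self):
        rng = np.random.default_rng(8)
        pair = make_pair(8, dd_layers=2)
        x = Tensor(rng.normal(size=(3, 8)))
        q, _, _ = pair.left.apply_dd_stack(x, x, x)
        expect = pair.left.dd_q[1](pair.left.dd_q[0](x))
        np.testing.assert_allclose(q.data, expect.data, atol=1e-12)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(dd_layers=3)


class TestFuseInputs:
    def test_zero_right_branch(self):
        rng = np.random.default_rng(9)
        pair = make_pair(9)
        a = Tensor(rng.normal(size=(3, 8)))
        z = Tensor(np.zeros((3, 8)))
        ql, kl, vl, qr, kr = pair.fuse_inputs(a, a, a, z, z, z)
        np.testing.assert_allclose(ql.data, pair.ln_q_left(a).data, atol=1e-12)
        np.testing.assert_allclose(vl.data, a.data, atol=1e-12)

    def test_equal_branches_double_before_norm(self):
        rng = np.random.default_rng(9)
        pair = make_pair(9)
        a = Tensor(rng.normal(size=(3, 8)))
        ql, _, vl, _, _ = pair.fuse_inputs(a, a, a, a, a, a)
        np.testing.assert_allclose(ql.data, pair.ln_q_left(a * 2.0).data,
                                   atol=1e-12)
        np.testing.assert_allclose(vl.data, 2 * a.data, atol=1e-12)

    def test_matches_composition_oracle(self):
        rng = np.random.default_rng(9)
        pair = make_pair(9)
        ts = [Tensor(rng.normal(size=(4, 8))) for _ in range(6)]
        ql, kl, vl, qr, kr = pair.fuse_inputs(*ts)
        np.testing.assert_allclose(ql.data,
                                   pair.ln_q_left(ts[0] + ts[3]).data, atol=1e-12)
        np.testing.assert_allclose(kl.data,
                                   pair.ln_k_left(ts[1] + ts[4]).data, atol=1e-12)
        np.testing.assert_allclose(vl.data, (ts[2] + ts[5]).data, atol=1e-12)
        np.testing.assert_allclose(qr.data, pair.ln_q_right(ts[3]).data,
                                   atol=1e-12)
        np.testing.assert_allclose(kr.data, pair.ln_k_right(ts[4]).data,
                                   atol=1e-12)


class TestLeftRightAttention:
    def test_left_single_token_is_projected_value(self):
        rng = np.random.default_rng(10)
        pair = make_pair(10)
        q, k, v = (Tensor(rng.normal(size=(1, 8))) for _ in range(3))
        out = pair.left_attention(q, k, v)
        np.testing.assert_allclose(out.data,
                                   pair.attn_left.out_proj(v).data, atol=1e-12)

    def test_left_zero_values_zero_output(self):
        pair = make_pair(10)
        pair.attn_left.out_proj.bias.data[:] = 0
        rng = np.random.default_rng(10)
        q, k = (Tensor(rng.normal(size=(3, 8))) for _ in range(2))
        out = pair.left_attention(q, k, Tensor(np.zeros((3, 8))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_right_reduces_to_self_attention_when_left_output_zero(self):
        rng = np.random.default_rng(11)
        pair = make_pair(11)
        q, k, v = (Tensor(rng.normal(size=(3, 8))) for _ in range(3))
        zero = Tensor(np.zeros((3, 8)))
        a = pair.right_attention(q, k, v, zero)
        b = pair.attn_right(q, k, v)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_right_single_token_closed_form(self):
        rng = np.random.default_rng(11)
        pair = make_pair(11)
        q, k, v, o = (Tensor(rng.normal(size=(1, 8))) for _ in range(4))
        out = pair.right_attention(q, k, v, o)
        np.testing.assert_allclose(
            out.data, pair.attn_right.out_proj(v + o).data, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        pair = make_pair(11)
        t = Tensor(np.zeros((3, 8)))
        with pytest.raises(ValueError):
            pair.right_attention(t, t, t, Tensor(np.zeros((2, 8))))


class TestCPMHSAForward:
    def test_zeroed_output_projections_give_zero(self):
        pair = make_pair(12)
        for attn in (pair.attn_left, pair.attn_right):
            attn.out_proj.weight.data[:] = 0
            attn.out_proj.bias.data[:] = 0
        x = Tensor(np.random.default_rng(12).normal(size=(4, 8)))
        np.testing.assert_allclose(pair(x).data, 0.0, atol=1e-12)

    def test_matches_chained_oracle(self):
        rng = np.random.default_rng(13)
        pair = make_pair(13)
        x = Tensor(rng.normal(size=(5, 8)))
        ql, kl, vl = pair.left.apply_dd_stack(*pair.left.project(x))
        qr, kr, vr = pair.right.apply_dd_stack(*pair.right.project(x))
        fql, fkl, fvl, fqr, fkr = pair.fuse_inputs(ql, kl, vl, qr, kr, vr)
        o_left = pair.left_attention(fql, fkl, fvl)
        o_right = pair.right_attention(fqr, fkr, vr, o_left)
        np.testing.assert_allclose(pair(x).data, (o_left + o_right).data,
                                   atol=1e-12)

    def test_every_parameter_receives_gradient(self):
        rng = np.random.default_rng(12)
        layer = CPTLayer(small_cfg(), rng)
        layer.eval()
        x = Tensor(rng.normal(size=(4, 8)))
        loss = (layer(x) ** 2).sum()
        loss.backward()
        for name, p in layer.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_left_value_weights_influence_right_output(self):
        # Finite-difference probe of the cross coupling: perturbing only
        # the left branch's value projection must change O_right.
        rng = np.random.default_rng(14)
        pair = make_pair(14)
        x = Tensor(rng.normal(size=(3, 8)))

        def right_out():
            ql, kl, vl = pair.left.apply_dd_stack(*pair.left.project(x))
            qr, kr, vr = pair.right.apply_dd_stack(*pair.right.project(x))
            fql, fkl, fvl, fqr, fkr = pair.fuse_inputs(ql, kl, vl, qr, kr, vr)
            o_left = pair.left_attention(fql, fkl, fvl)
            return pair.right_attention(fqr, fkr, vr, o_left).data.copy()

        base = right_out()
        pair.left.v_proj.weight.data[0, 0] += 1e-3
        assert np.abs(right_out() - base).max() > 0


class TestCPTLayer:
    def test_zeroed_attention_reduces_to_activation_block(self):
        pair_cfg = small_cfg()
        layer = CPTLayer(pair_cfg, np.random.default_rng(15))
        layer.eval()
        for pair in layer.cpmhsa.pairs:
            for attn in (pair.attn_left, pair.attn_right):
                attn.out_proj.weight.data[:] = 0
                attn.out_proj.bias.data[:] = 0
        x = Tensor(np.random.default_rng(15).normal(size=(4, 8)))
        np.testing.assert_allclose(layer(x).data, layer.ffn(x).data, atol=1e-12)

    @pytest.mark.parametrize("n_tokens", [1, 3, 9])
    def test_token_count_equivariance(self, n_tokens):
        layer = CPTLayer(small_cfg(), np.random.default_rng(16))
        layer.eval()
        x = Tensor(np.random.default_rng(16).normal(size=(n_tokens, 8)))
        assert layer(x).shape == (n_tokens, 8)

    def test_two_layer_stack_equals_sequential_application(self):
        rng = np.random.default_rng(14)
        stack = build_cpt_stack(small_cfg(depth=2), rng)
        for l in stack:
            l.eval()
        x = Tensor(rng.normal(size=(4, 8)))
        manual = stack[1](stack[0](x))
        out = x
        for layer in stack:
            out = layer(out)
        np.testing.assert_allclose(out.data, manual.data, atol=1e-12)

    def test_mlp_variants_apply_parallel_residual_blocks(self):
        rng = np.random.default_rng(17)
        layer = CPTLayer(small_cfg(mlp_layers=2), rng)
        layer.eval()
        x = Tensor(rng.normal(size=(3, 8)))
        z_prime = layer.cpmhsa(x) + x
        expect = z_prime + layer.mlps[0](z_prime) + layer.mlps[1](z_prime)
        np.testing.assert_allclose(layer(x).data, expect.data, atol=1e-12)

    def test_eval_forward_bitwise_deterministic(self):
        layer = CPTLayer(small_cfg(dropout=0.1), np.random.default_rng(18))
        layer.eval()
        x = Tensor(np.random.default_rng(18).normal(size=(5, 8)))
        assert np.array_equal(layer(x).data, layer(x).data)

    def test_odd_parallelism_adds_solo_branch(self):
        m = CPMHSA(small_cfg(parallelism=3), np.random.default_rng(19))
        assert len(m.pairs) == 1 and m.solo is not None
        m.eval()
        x = Tensor(np.random.default_rng(19).normal(size=(3, 8)))
        expect = m.pairs[0](x) + m.solo(x)
        np.testing.assert_allclose(m(x).data, expect.data, atol=1e-12)


def test_per_layer_parameter_count_closed_form():
    """Canonical block: 2 branches x (LN + 3 proj + 3 DD + out proj +
    2 fusion LNs) + activation LN, at ViT-Base width."""
    cfg = CPTConfig(depth=1, parallelism=2, dd_layers=1, mlp_layers=0)
    layer = CPTLayer(cfg, np.random.default_rng(0))
    d = 768
    branch = 2 * d + 3 * (d * d + d) + 3 * (d * d + d) + (d * d + d) + 2 * 2 * d
    assert layer.n_parameters() == 2 * branch + 2 * d
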