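"""The cross-parallel transformer (C-PT) block.

A C-PT layer replaces the serial pre-norm ViT layer with a two-branch
cross-parallel multi-head self-attention (C-PMHSA) followed by a bare
LayerNorm+GELU activation block instead of the feed-forward MLP:

* each branch layer-normalizes the shared input and projects it to its
  own Q/K/V, optionally refined by a stack of Dendrite-Net (DD) gating
  layers;
* the branches' Q/K/V are fused additively into the left branch (with
  fresh layer norms on the fused Q and K), so the left attention sees
  both branches' features;
* the right branch attends with its own (normalized) Q/K and a value
  matrix augmented by the left branch's output — self-*cross* attention:
  the left result steers which features the right branch propagates;
* the two outputs are summed, added residually to the input, and passed
  through ``GELU(LN(.))`` (or through 1-2 parallel MLP blocks in the
  ablation variants).

The canonical cross pattern is defined for exactly two branches; wider
parallelism is provided as a sum of independent cross-pairs (with a
plain self-attention branch when the branch count is odd) and is marked
non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import engine, nn
from .attention_core import (DDLayer, MultiHeadAttention, MLPBlock,
                             ActivationBlock)
from .engine import Tensor


@dataclass
class CPTConfig:
    """Hyperparameters of a transformer stack (any variant).

    ``depth`` stacked layers of ``parallelism`` branches each; hidden
    size / heads / MLP width default to ViT-Base (768 / 12 / 3072).
    ``dd_layers`` and ``mlp_layers`` select the ablation variants: the
    canonical C-PT block is ``dd_layers=1, mlp_layers=0`` (activation
    block only).
    """

    depth: int = 7
    parallelism: int = 2
    dd_layers: int = 1
    mlp_layers: int = 0
    hidden_dim: int = 768
    heads: int = 12
    mlp_dim: int = 3072
    dropout: float = 0.1
    bias: bool = True
    eps: float = 1e-6
    activation_residual: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.parallelism < 1:
            raise ValueError(f"parallelism must be >= 1, got {self.parallelism}")
        if self.dd_layers not in (0, 1, 2):
            raise ValueError(f"dd_layers must be in {{0,1,2}}, got {self.dd_layers}")
        if self.mlp_layers not in (0, 1, 2):
            raise ValueError(f"mlp_layers must be in {{0,1,2}}, got {self.mlp_layers}")
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CPTConfig":
        return cls(**d)


class CPTBranch(nn.Module):
    """One branch: input LN, Q/K/V projections and a DD gating stack."""

    def __init__(self, cfg: CPTConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.hidden_dim
        self.norm_in = nn.LayerNorm(d, eps=cfg.eps)
        self.q_proj = nn.Linear(d, d, rng, bias=cfg.bias)
        self.k_proj = nn.Linear(d, d, rng, bias=cfg.bias)
        self.v_proj = nn.Linear(d, d, rng, bias=cfg.bias)
        self.dd_q = nn.ModuleList(DDLayer(d, rng, bias=cfg.bias)
                                  for _ in range(cfg.dd_layers))
        self.dd_k = nn.ModuleList(DDLayer(d, rng, bias=cfg.bias)
                                  for _ in range(cfg.dd_layers))
        self.dd_v = nn.ModuleList(DDLayer(d, rng, bias=cfg.bias)
                                  for _ in range(cfg.dd_layers))

    def project(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Q/K/V of the layer-normalized input (one LN shared by all three)."""
        h = self.norm_in(x)
        return self.q_proj(h), self.k_proj(h), self.v_proj(h)

    def apply_dd_stack(self, q: Tensor, k: Tensor, v: Tensor):
        """Sequentially apply the DD gate stack to each of Q, K, V."""
        for dd in self.dd_q:
            q = dd(q)
        for dd in self.dd_k:
            k = dd(k)
        for dd in self.dd_v:
            v = dd(v)
        return q, k, v


class CrossPair(nn.Module):
    """The canonical two-branch C-PMHSA."""

    def __init__(self, cfg: CPTConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.hidden_dim
        self.left = CPTBranch(cfg, rng)
        self.right = CPTBranch(cfg, rng)
        # fusion norms are fresh parameterized norms, not reuses of the
        # branch input norms
        self.ln_q_left = nn.LayerNorm(d, eps=cfg.eps)
        self.ln_k_left = nn.LayerNorm(d, eps=cfg.eps)
        self.ln_q_right = nn.LayerNorm(d, eps=cfg.eps)
        self.ln_k_right = nn.LayerNorm(d, eps=cfg.eps)
        self.attn_left = MultiHeadAttention(d, cfg.heads, rng,
                                            softmax_dropout=cfg.dropout,
                                            output_dropout=cfg.dropout,
                                            bias=cfg.bias)
        self.attn_right = MultiHeadAttention(d, cfg.heads, rng,
                                             softmax_dropout=cfg.dropout,
                                             output_dropout=cfg.dropout,
                                             bias=cfg.bias)

    def fuse_inputs(self, ql, kl, vl, qr, kr, vr):
        """Additive fusion into the left branch; fresh LNs on fused Q/K.

        The fused value matrix is a plain sum (no normalization); the
        right branch's Q/K are normalized but not fused.
        """
        q_left = self.ln_q_left(ql + qr)
        k_left = self.ln_k_left(kl + kr)
        v_left = vl + vr
        q_right = self.ln_q_right(qr)
        k_right = self.ln_k_right(kr)
        return q_left, k_left, v_left, q_right, k_right

    def left_attention(self, q_left, k_left, v_left) -> Tensor:
        return self.attn_left(q_left, k_left, v_left)

    def right_attention(self, q_right, k_right, v_hat_right, o_left) -> Tensor:
        """Self-cross attention: left output is folded into the right values."""
        if v_hat_right.shape != o_left.shape:
            raise ValueError("left output / right value shape mismatch")
        return self.attn_right(q_right, k_right, v_hat_right + o_left)

    def forward(self, z: Tensor) -> Tensor:
        ql, kl, vl = self.left.apply_dd_stack(*self.left.project(z))
        qr, kr, vr = self.right.apply_dd_stack(*self.right.project(z))
        q_left, k_left, v_left, q_right, k_right = self.fuse_inputs(
            ql, kl, vl, qr, kr, vr)
        o_left = self.left_attention(q_left, k_left, v_left)
        o_right = self.right_attention(q_right, k_right, vr, o_left)
        return o_left + o_right


class SoloBranch(nn.Module):
    """Plain self-attention branch (with DD stack) for odd parallelism."""

    def __init__(self, cfg: CPTConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.hidden_dim
        self.branch = CPTBranch(cfg, rng)
        self.ln_q = nn.LayerNorm(d, eps=cfg.eps)
        self.ln_k = nn.LayerNorm(d, eps=cfg.eps)
        self.attn = MultiHeadAttention(d, cfg.heads, rng,
                                       softmax_dropout=cfg.dropout,
                                       output_dropout=cfg.dropout, bias=cfg.bias)

    def forward(self, z: Tensor) -> Tensor:
        q, k, v = self.branch.apply_dd_stack(*self.branch.project(z))
        return self.attn(self.ln_q(q), self.ln_k(k), v)


class CPMHSA(nn.Module):
    """Cross-parallel MHSA: sum of cross-pairs (plus a solo odd branch)."""

    def __init__(self, cfg: CPTConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.parallelism < 2:
            raise ValueError("C-PMHSA needs parallelism >= 2")
        self.pairs = nn.ModuleList(CrossPair(cfg, rng)
                                   for _ in range(cfg.parallelism // 2))
        self.solo = SoloBranch(cfg, rng) if cfg.parallelism % 2 else None

    def forward(self, z: Tensor) -> Tensor:
        out = None
        for pair in self.pairs:
            y = pair(z)
            out = y if out is None else out + y
        if self.solo is not None:
            out = out + self.solo(z)
        return out


class CPTLayer(nn.Module):
    """One C-PT layer: residual C-PMHSA plus the feed-forward stage.

    Canonical form (``mlp_layers=0``): ``z_out = GELU(LN(z + CPMHSA(z)))``
    with no residual around the activation block.  Ablation variants
    replace the activation block with 1 or 2 parallel MLP blocks applied
    residually (parallel-ViT style).
    """

    def __init__(self, cfg: CPTConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cfg = cfg
        self.cpmhsa = CPMHSA(cfg, rng)
        if cfg.mlp_layers == 0:
            self.ffn = ActivationBlock(cfg.hidden_dim,
                                       residual=cfg.activation_residual,
                                       eps=cfg.eps)
            self.mlps = None
        else:
            self.ffn = None
            self.mlps = nn.ModuleList(
                MLPBlock(cfg.hidden_dim, cfg.mlp_dim, rng,
                         bias=cfg.bias, eps=cfg.eps)
                for _ in range(cfg.mlp_layers))

    def forward(self, z: Tensor) -> Tensor:
        z_prime = self.cpmhsa(z) + z
        if self.mlps is None:
            return self.ffn(z_prime)
        out = z_prime
        for mlp in self.mlps:
            out = out + mlp(z_prime)
        return out


def build_cpt_stack(cfg: CPTConfig, rng: np.random.Generator) -> nn.ModuleList:
    """``cfg.depth`` independent C-PT layers."""
    return nn.ModuleList(CPTLayer(cfg, rng) for _ in range(cfg.depth))
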