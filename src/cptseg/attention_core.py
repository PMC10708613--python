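"""Primitive transformer operators shared by every network variant.

Contains the building blocks of both the serial/parallel ViT baselines
and the cross-parallel transformer: layer normalization, the Dendrite-Net
(DD) gating layer, scaled dot-product attention, multi-head attention,
the feed-forward MLP block, the bare LayerNorm+GELU activation block that
replaces it, and the serial / parallel pre-norm ViT layers.

Token sequences are plain ``(N, d)`` tensors (N tokens, d channels);
all modules are shape-preserving on that contract and accept a leading
batch axis as well.
"""

from __future__ import annotations

import math

import numpy as np

from . import engine, nn
from .engine import Tensor


class DDLayer(nn.Module):
    """Dendrite-Net layer: a Hadamard gate with a linear residual.

    Computes ``(Wx) * x + Wx`` where ``*`` is the element-wise product:
    the linear map modulates its own input multiplicatively (suppressing
    low-interest features) and its output is added back so that gated-out
    features are not lost entirely.  The same weight matrix appears in
    both terms.  The map must be square (d -> d).
    """

    def __init__(self, dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.dim = dim
        self.linear = nn.Linear(dim, dim, rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.dim:
            raise ValueError(f"DDLayer is a square {self.dim}->{self.dim} map, "
                             f"got input dim {x.shape[-1]}")
        wx = self.linear(x, category="linear")
        if engine._ACTIVE_COUNTER is not None:
            engine._record_macs("hadamard", int(np.prod(x.shape)))
        return wx * x + wx


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, d_k: int,
                         softmax_dropout: nn.Dropout | None = None) -> Tensor:
    """``softmax(Q K^T / sqrt(d_k)) V`` with optional post-softmax dropout.

    Works on ``(..., N, d)`` stacks; the leading axes (batch, heads) are
    broadcast through the two matrix products.
    """
    if d_k <= 0:
        raise ValueError(f"d_k must be positive, got {d_k}")
    scores = engine.matmul(q, _swap_last(k), category="attn_matmul")
    weights = engine.softmax(scores * (1.0 / math.sqrt(d_k)), axis=-1)
    if softmax_dropout is not None:
        weights = softmax_dropout(weights)
    return engine.matmul(weights, v, category="attn_matmul")


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(*axes)


class MultiHeadAttention(nn.Module):
    """Multi-head attention over already-projected Q/K/V token sequences.

    The inputs are split channel-wise into ``h`` disjoint head subspaces
    of width ``d_k = d/h`` (the per-head maps of the standard formulation
    are realised by the upstream Q/K/V projections, as in common ViT
    implementations), attended independently, concatenated and passed
    through the output projection, followed by output dropout.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 softmax_dropout: float = 0.1, output_dropout: float = 0.1,
                 bias: bool = True):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.d_k = dim // n_heads
        self.out_proj = nn.Linear(dim, dim, rng, bias=bias)
        self.drop_soft = nn.Dropout(softmax_dropout, np.random.default_rng(rng.integers(2**31)))
        self.drop_out = nn.Dropout(output_dropout, np.random.default_rng(rng.integers(2**31)))

    def _split(self, t: Tensor) -> Tensor:
        n, d = t.shape[-2], t.shape[-1]
        lead = t.shape[:-2]
        t = t.reshape(*lead, n, self.n_heads, self.d_k)
        axes = list(range(t.ndim))
        axes[-3], axes[-2] = axes[-2], axes[-3]
        return t.transpose(*axes)          # (..., h, N, d_k)

    def _merge(self, t: Tensor) -> Tensor:
        axes = list(range(t.ndim))
        axes[-3], axes[-2] = axes[-2], axes[-3]
        t = t.transpose(*axes)             # (..., N, h, d_k)
        lead = t.shape[:-3]
        return t.reshape(*lead, t.shape[-3], self.dim)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        heads = scaled_dot_attention(self._split(q), self._split(k),
                                     self._split(v), self.d_k, self.drop_soft)
        return self.drop_out(self.out_proj(self._merge(heads)))


class MLPBlock(nn.Module):
    """Pre-norm transformer feed-forward block: LN -> d->d_mlp -> GELU -> d_mlp->d."""

    def __init__(self, dim: int, mlp_dim: int, rng: np.random.Generator,
                 bias: bool = True, eps: float = 1e-6):
        super().__init__()
        self.norm = nn.LayerNorm(dim, eps=eps)
        self.fc1 = nn.Linear(dim, mlp_dim, rng, bias=bias)
        self.fc2 = nn.Linear(mlp_dim, dim, rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(engine.gelu(self.fc1(self.norm(x))))


class ActivationBlock(nn.Module):
    """The stripped feed-forward replacement: ``GELU(LN(x))``, nothing else.

    No learned linear maps and no residual by default; a residual can be
    enabled for ablation experiments.
    """

    def __init__(self, dim: int, residual: bool = False, eps: float = 1e-6):
        super().__init__()
        self.norm = nn.LayerNorm(dim, eps=eps)
        self.residual = residual

    def forward(self, x: Tensor) -> Tensor:
        y = engine.gelu(self.norm(x))
        return y + x if self.residual else y


class SelfAttentionBlock(nn.Module):
    """Pre-norm self-attention residual branch: LN -> QKV proj -> MHSA."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.1, bias: bool = True, eps: float = 1e-6):
        super().__init__()
        self.norm = nn.LayerNorm(dim, eps=eps)
        self.q_proj = nn.Linear(dim, dim, rng, bias=bias)
        self.k_proj = nn.Linear(dim, dim, rng, bias=bias)
        self.v_proj = nn.Linear(dim, dim, rng, bias=bias)
        self.attn = MultiHeadAttention(dim, n_heads, rng,
                                       softmax_dropout=dropout,
                                       output_dropout=dropout, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x)
        return self.attn(self.q_proj(h), self.k_proj(h), self.v_proj(h))


class SerialViTLayer(nn.Module):
    """Standard pre-norm transformer layer: x + MHSA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, dim: int = 768, n_heads: int = 12, mlp_dim: int = 3072,
                 rng: np.random.Generator | None = None, dropout: float = 0.1,
                 bias: bool = True, eps: float = 1e-6):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.attn_block = SelfAttentionBlock(dim, n_heads, rng,
                                             dropout=dropout, bias=bias, eps=eps)
        self.mlp_block = MLPBlock(dim, mlp_dim, rng, bias=bias, eps=eps)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn_block(x)
        return x + self.mlp_block(x)


class ParallelViTLayer(nn.Module):
    """Parallel ViT layer: B independent residual branches summed per sub-layer.

    ``x' = x + sum_b MHSA_b(LN_b(x))`` then ``x' + sum_b MLP_b(LN_b(x'))``.
    Trades depth for width: stacking L of these with B branches costs
    exactly as many parameters as L*B serial layers.
    """

    def __init__(self, branches: int, dim: int = 768, n_heads: int = 12,
                 mlp_dim: int = 3072, rng: np.random.Generator | None = None,
                 dropout: float = 0.1, bias: bool = True, eps: float = 1e-6):
        super().__init__()
        if branches < 2:
            raise ValueError(f"parallel layer needs >= 2 branches, got {branches}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.attn_branches = nn.ModuleList(
            SelfAttentionBlock(dim, n_heads, rng, dropout=dropout,
                               bias=bias, eps=eps) for _ in range(branches))
        self.mlp_branches = nn.ModuleList(
            MLPBlock(dim, mlp_dim, rng, bias=bias, eps=eps)
            for _ in range(branches))

    def forward(self, x: Tensor) -> Tensor:
        s = x
        for b in self.attn_branches:
            s = s + b(x)
        x = s
        s = x
        for b in self.mlp_branches:
            s = s + b(x)
        return s
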