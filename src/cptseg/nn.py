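"""Neural-network modules over the autodiff engine.

Mirrors the familiar Module/Parameter idiom: modules register parameters
and child modules by attribute assignment, expose ``named_parameters`` /
``state_dict``, and carry a global train/eval flag that controls dropout.
Weight initialization follows the ViT convention — truncated normal
(std 0.02, clipped at two standard deviations) for linear and embedding
weights, He-normal for convolutions, ones/zeros for norms — and is fully
determined by the ``numpy`` Generator handed to the constructor.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import engine
from .engine import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) resampled until within +-2 std (exact truncation)."""
    if getattr(rng, "all_zero", False):
        return np.zeros(shape)
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode / grads -------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:3]} "
                           f"extra={sorted(extra)[:3]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Linear(Module):
    """Affine map on the trailing axis, ``y = x W^T + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        w = (np.zeros((out_features, in_features)) if zero_init
             else trunc_normal(rng, (out_features, in_features)))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor, category: str = "linear") -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expected last dim {self.in_features}, got {x.shape[-1]}")
        y = engine.matmul(x, self.weight.transpose(1, 0), category=category)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Row-wise normalization over the trailing feature axis, then affine."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.dim:
            raise ValueError(f"LayerNorm expected dim {self.dim}, got {x.shape[-1]}")
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / engine.sqrt(var + self.eps)
        return y * self.gain + self.shift


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode.

    Each instance owns a child Generator split off the build rng, so a
    fixed build seed gives a reproducible training trajectory.
    """

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return engine.gelu(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return engine.relu(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return engine.conv2d(x, self.weight, self.bias,
                             stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide into groups")
        self.groups = num_groups
        self.channels = num_channels
        self.eps = eps
        self.gain = Parameter(np.ones(num_channels))
        self.shift = Parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, (c // g) * h * w)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = (xc / engine.sqrt(var + self.eps)).reshape(b, c, h, w)
        return y * self.gain.reshape(1, c, 1, 1) + self.shift.reshape(1, c, 1, 1)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return engine.max_pool2d(x, self.kernel, self.stride, self.padding)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum and decoupled-into-gradient weight decay.

    Update: ``v = mu*v + (g + wd*theta); theta -= lr*v`` — the same
    semantics as the reference deep-learning frameworks, so published
    hyperparameters (lr 0.01, momentum 0.9, weight decay 1e-4) transfer.
    """

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
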