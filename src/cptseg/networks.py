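"""Full segmentation networks: TransUNet-style hybrid encoder-decoder.

Three variants share one skeleton and differ only in the transformer
stack:

* ``serial``        — stacked standard pre-norm ViT layers (the baseline),
* ``parallel_vit``  — depth-for-width recombination (L layers x B branches),
* ``cpt``           — cross-parallel transformer layers.

The skeleton is a truncated residual-bottleneck CNN that downsamples to
1/16 scale, a 1x1 patch embedding into d-dimensional tokens with learned
position embeddings, the transformer stack, and a cascaded-upsampler
(CUP) decoder that restores full resolution through four upsample+conv
stages consuming the CNN skip features.

The default CNN/decoder widths are a reconstruction: the transformer
stack is exactly ViT-Base, and the remaining widths were solved once so
that the whole network's parameter and MAC budgets match the published
totals of this architecture family (which imply a much lighter backbone
than the commonly distributed TransUNet truncation).  See
``docs/methods.md`` for the derivation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import engine, nn
from .attention_core import SerialViTLayer, ParallelViTLayer
from .cpt_module import CPTConfig, CPTLayer
from .engine import Tensor

VARIANTS = ("serial", "parallel_vit", "cpt")

# organ label order of the abdominal multi-organ protocol
CLASS_NAMES = ("background", "aorta", "gallbladder", "left_kidney",
               "right_kidney", "liver", "pancreas", "spleen", "stomach")


@dataclass
class SegVolume:
    """A stacked-slice case: intensities, integer labels, voxel spacing."""

    case_id: str
    slices: np.ndarray          # (S, H, W) float in [0, 1]
    labels: np.ndarray          # (S, H, W) int in [0, n_classes)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # (slice, row, col) mm

    def __post_init__(self):
        if self.slices.shape != self.labels.shape:
            raise ValueError("slices and labels must be shape-aligned")


@dataclass
class NetworkConfig:
    variant: str = "cpt"
    image_size: int = 224
    patch_size: int = 16
    n_classes: int = 9
    in_channels: int = 1
    transformer: CPTConfig = field(default_factory=CPTConfig)
    # hybrid CNN encoder (half-width 3-stage residual bottleneck)
    root_width: int = 64
    cnn_stage_units: tuple[int, ...] = (3, 4, 10)
    cnn_stage_mid: tuple[int, ...] = (32, 64, 128)
    cnn_stage_out: tuple[int, ...] = (128, 256, 512)
    # cascaded-upsampler decoder
    decoder_head_channels: int = 256
    decoder_channels: tuple[int, ...] = (256, 160, 48, 32)
    # position-embedding reference grid; kept size-independent and
    # bilinearly resized to the actual token grid
    pos_grid: int = 14

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; pick from {VARIANTS}")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.variant == "parallel_vit" and self.transformer.parallelism < 2:
            raise ValueError("parallel_vit requires parallelism >= 2")
        if self.variant == "serial" and self.transformer.parallelism != 1:
            raise ValueError("serial variant requires parallelism == 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def n_tokens(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if isinstance(d.get("transformer"), dict):
            d["transformer"] = CPTConfig.from_dict(d["transformer"])
        for k in ("cnn_stage_units", "cnn_stage_mid", "cnn_stage_out",
                  "decoder_channels"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def desk_scale(cls, variant: str = "cpt", image_size: int = 64,
                   depth: int = 2, **overrides) -> "NetworkConfig":
        """Reduced-width profile for CPU-scale training experiments."""
        tf = CPTConfig(depth=depth,
                       parallelism=1 if variant == "serial" else 2,
                       dd_layers=1, mlp_layers=0,
                       hidden_dim=96, heads=6, mlp_dim=384, dropout=0.0)
        cfg = dict(variant=variant, image_size=image_size, n_classes=9,
                   transformer=tf, root_width=16,
                   cnn_stage_units=(1, 1, 1), cnn_stage_mid=(8, 16, 32),
                   cnn_stage_out=(32, 64, 128),
                   decoder_head_channels=64, decoder_channels=(64, 32, 16, 16),
                   pos_grid=image_size // 16)
        cfg.update(overrides)
        return cls(**cfg)


# ---------------------------------------------------------------------------
# CNN encoder
# ---------------------------------------------------------------------------

def _gn_groups(ch: int) -> int:
    for g in (32, 16, 8, 4, 2):
        if ch % g == 0:
            return g
    return 1


class ConvNormRelu(nn.Module):
    def __init__(self, cin, cout, kernel, rng, stride=1, padding=0):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, rng, stride=stride,
                              padding=padding, bias=False)
        self.norm = nn.GroupNorm(_gn_groups(cout), cout)

    def forward(self, x):
        return engine.relu(self.norm(self.conv(x)))


class BottleneckUnit(nn.Module):
    """Pre-activation residual bottleneck (1x1 -> 3x3 -> 1x1)."""

    def __init__(self, cin, cmid, cout, rng, stride=1):
        super().__init__()
        self.norm1 = nn.GroupNorm(_gn_groups(cin), cin)
        self.conv1 = nn.Conv2d(cin, cmid, 1, rng, bias=False)
        self.norm2 = nn.GroupNorm(_gn_groups(cmid), cmid)
        self.conv2 = nn.Conv2d(cmid, cmid, 3, rng, stride=stride, padding=1,
                               bias=False)
        self.norm3 = nn.GroupNorm(_gn_groups(cmid), cmid)
        self.conv3 = nn.Conv2d(cmid, cout, 1, rng, bias=False)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
        else:
            self.proj = None

    def forward(self, x):
        h = engine.relu(self.norm1(x))
        shortcut = x if self.proj is None else self.proj(h)
        h = self.conv1(h)
        h = self.conv2(engine.relu(self.norm2(h)))
        h = self.conv3(engine.relu(self.norm3(h)))
        return h + shortcut


class HybridEncoder(nn.Module):
    """Truncated bottleneck CNN + patch/position embedding to tokens."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.transformer.hidden_dim
        self.root = ConvNormRelu(cfg.in_channels, cfg.root_width, 7, rng,
                                 stride=2, padding=3)
        self.pool = nn.MaxPool2d(3, 2, padding=1)
        stages = []
        cin = cfg.root_width
        for i, (units, cmid, cout) in enumerate(zip(
                cfg.cnn_stage_units, cfg.cnn_stage_mid, cfg.cnn_stage_out)):
            blocks = [BottleneckUnit(cin, cmid, cout, rng,
                                     stride=1 if i == 0 else 2)]
            blocks += [BottleneckUnit(cout, cmid, cout, rng)
                       for _ in range(units - 1)]
            stages.append(nn.Sequential(*blocks))
            cin = cout
        self.stages = nn.ModuleList(stages)
        self.patch_embed = nn.Conv2d(cfg.cnn_stage_out[-1], d, 1, rng, bias=True)
        self.pos_embed = nn.Parameter(
            nn.trunc_normal(rng, (1, cfg.pos_grid * cfg.pos_grid, d)))

    def forward(self, image: Tensor) -> tuple[Tensor, list[Tensor]]:
        cfg = self.cfg
        if image.shape[-1] != cfg.image_size or image.shape[-2] != cfg.image_size:
            raise ValueError(f"expected {cfg.image_size}^2 input, "
                             f"got {image.shape[-2:]}")
        x = self.root(image)
        skips = [x]                       # 1/2 scale
        x = self.pool(x)
        for stage in list(self.stages)[:-1]:
            x = stage(x)
            skips.append(x)               # 1/4, 1/8 scales
        x = self.stages[-1](x)            # 1/16 scale
        feat = self.patch_embed(x)        # (B, d, g, g)
        b, d, g, _ = feat.shape
        tokens = feat.reshape(b, d, g * g).transpose(0, 2, 1)
        tokens = tokens + self._positions(g)
        return tokens, skips[::-1]        # skips deepest-first

    def _positions(self, grid: int) -> Tensor:
        pe = self.pos_embed
        if grid == self.cfg.pos_grid:
            return pe
        d = pe.shape[-1]
        pe_map = pe.reshape(1, self.cfg.pos_grid, self.cfg.pos_grid, d)
        pe_map = pe_map.transpose(0, 3, 1, 2)
        pe_map = engine.upsample_bilinear(pe_map, (grid, grid))
        return pe_map.reshape(1, d, grid * grid).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# CUP decoder
# ---------------------------------------------------------------------------

class DecoderBlock(nn.Module):
    """Upsample x2 (bilinear), concatenate the skip, two 3x3 convs."""

    def __init__(self, cin, skip_ch, cout, rng):
        super().__init__()
        self.conv1 = ConvNormRelu(cin + skip_ch, cout, 3, rng, padding=1)
        self.conv2 = ConvNormRelu(cout, cout, 3, rng, padding=1)

    def forward(self, x, skip=None):
        h, w = x.shape[-2:]
        x = engine.upsample_bilinear(x, (2 * h, 2 * w))
        if skip is not None:
            x = engine.concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


class CUPDecoder(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.transformer.hidden_dim
        self.cfg = cfg
        self.conv_more = ConvNormRelu(d, cfg.decoder_head_channels, 3, rng,
                                      padding=1)
        skip_chs = list(cfg.cnn_stage_out[-2::-1]) + [cfg.root_width, 0]
        cin = cfg.decoder_head_channels
        blocks = []
        for cout, sk in zip(cfg.decoder_channels, skip_chs):
            blocks.append(DecoderBlock(cin, sk, cout, rng))
            cin = cout
        self.blocks = nn.ModuleList(blocks)
        self.head = nn.Conv2d(cin, cfg.n_classes, 3, rng, padding=1, bias=True)

    def forward(self, tokens: Tensor, skips: list[Tensor]) -> Tensor:
        b, n, d = tokens.shape
        g = int(round(n ** 0.5))
        if g * g != n:
            raise ValueError(f"token count {n} is not a perfect square")
        x = tokens.transpose(0, 2, 1).reshape(b, d, g, g)
        x = self.conv_more(x)
        feeds = list(skips) + [None] * (len(self.blocks) - len(skips))
        for block, skip in zip(self.blocks, feeds):
            x = block(x, skip)
        return self.head(x)


# ---------------------------------------------------------------------------
# Whole models
# ---------------------------------------------------------------------------

def _build_stack(cfg: NetworkConfig, rng: np.random.Generator) -> nn.ModuleList:
    t = cfg.transformer
    if cfg.variant == "serial":
        return nn.ModuleList(
            SerialViTLayer(t.hidden_dim, t.heads, t.mlp_dim, rng,
                           dropout=t.dropout, bias=t.bias, eps=t.eps)
            for _ in range(t.depth))
    if cfg.variant == "parallel_vit":
        return nn.ModuleList(
            ParallelViTLayer(t.parallelism, t.hidden_dim, t.heads, t.mlp_dim,
                             rng, dropout=t.dropout, bias=t.bias, eps=t.eps)
            for _ in range(t.depth))
    return nn.ModuleList(CPTLayer(t, rng) for _ in range(t.depth))


class SegModel(nn.Module):
    """Hybrid encoder -> transformer stack -> CUP decoder."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = HybridEncoder(cfg, rng)
        self.transformer = _build_stack(cfg, rng)
        self.encoder_norm = nn.LayerNorm(cfg.transformer.hidden_dim,
                                         eps=cfg.transformer.eps)
        self.decoder = CUPDecoder(cfg, rng)

    def hybrid_encode(self, image: Tensor) -> tuple[Tensor, list[Tensor]]:
        return self.encoder(image)

    def transform(self, tokens: Tensor) -> Tensor:
        for layer in self.transformer:
            tokens = layer(tokens)
        return self.encoder_norm(tokens)

    def decode_cup(self, tokens: Tensor, skips: list[Tensor]) -> Tensor:
        return self.decoder(tokens, skips)

    def forward(self, image: Tensor) -> Tensor:
        tokens, skips = self.hybrid_encode(image)
        tokens = self.transform(tokens)
        return self.decode_cup(tokens, skips)

    def forward_logits(self, image: Tensor) -> Tensor:
        return self.forward(image)


def build_model(cfg: NetworkConfig, seed: int | None = 0,
                init: str = "random") -> SegModel:
    """Instantiate a network with deterministic seeded initialization.

    ``init='zeros'`` skips random initialization (parameter values all
    zero); useful when only the architecture matters, e.g. accounting.
    """
    if init not in ("random", "zeros"):
        raise ValueError("init must be 'random' or 'zeros'")
    if init == "zeros":
        rng = _ZeroGenerator()
    else:
        rng = np.random.default_rng(seed)
    return SegModel(cfg, rng)


class _ZeroGenerator(np.random.Generator):
    """A Generator whose draws are all zero — for value-free instantiation."""

    all_zero = True

    def __init__(self):
        super().__init__(np.random.PCG64(0))

    def normal(self, loc=0.0, scale=1.0, size=None):
        return np.zeros(size if size is not None else ())

    def integers(self, *args, **kwargs):
        return 0

    def random(self, size=None):
        return np.zeros(size if size is not None else ())


def forward_segment(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Evaluation-mode per-pixel class probabilities for one slice.

    ``image`` is (H, W) or (1, H, W); returns (n_classes, H, W) softmax
    probabilities.
    """
    model.eval()
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    logits = model(Tensor(arr[None]))
    probs = engine.softmax(logits, axis=1)
    return probs.data[0]


def predict_labels(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Argmax label map for one slice."""
    return forward_segment(model, image).argmax(axis=0)


def predict_volume(model: SegModel, volume: SegVolume) -> np.ndarray:
    """Slice-wise inference stacked back into a (S, H, W) label volume."""
    return np.stack([predict_labels(model, s) for s in volume.slices])
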