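"""Desk-scale training and inference harness.

Optimization follows the published recipe for this model family: SGD
with learning rate 0.01, momentum 0.9 and weight decay 1e-4, on a
combined cross-entropy + soft-Dice loss over per-pixel class logits,
with random-rotation/flip augmentation.  Two profiles exist: the
full published recipe (batch 24, 14k iterations — provided for
fidelity, far beyond a desk CPU) and a desk-scale profile (batch 4,
500 iterations, reduced-width networks) used by the tests and examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import engine, nn
from .engine import Tensor
from .networks import (NetworkConfig, SegModel, SegVolume, build_model,
                       predict_volume)


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 24
    max_iterations: int = 14000
    seed: int = 0
    augment_rotate: bool = True
    augment_flip: bool = True
    rotate_degrees: float = 20.0
    ce_weight: float = 0.5
    dice_weight: float = 0.5
    log_every: int = 10

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        base = dict(batch_size=4, max_iterations=500, log_every=10)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross entropy; labels (B,H,W) int, logits (B,C,H,W)."""
    b, c, h, w = logits.shape
    m = Tensor(logits.data.max(axis=1, keepdims=True))
    shifted = logits - m
    lse = engine.log(engine.exp(shifted).sum(axis=1, keepdims=True))
    log_probs = shifted - lse
    onehot = np.zeros((b, c, h, w))
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / (b * h * w))


def soft_dice_loss(logits: Tensor, labels: np.ndarray,
                   smooth: float = 1e-5) -> Tensor:
    """1 - mean soft Dice over all classes (softmax probs vs one-hot)."""
    b, c, h, w = logits.shape
    probs = engine.softmax(logits, axis=1)
    onehot = np.zeros((b, c, h, w))
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    target = Tensor(onehot)
    inter = (probs * target).sum(axis=(0, 2, 3))
    sizes = probs.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + smooth) / (sizes + smooth)
    return 1.0 - dice.mean()


def combined_loss(logits: Tensor, labels: np.ndarray,
                  tc: TrainConfig) -> tuple[Tensor, float, float]:
    ce = cross_entropy_loss(logits, labels)
    dl = soft_dice_loss(logits, labels)
    return tc.ce_weight * ce + tc.dice_weight * dl, ce.item(), dl.item()


# ---------------------------------------------------------------------------
# Data pipeline
# ---------------------------------------------------------------------------

def _slice_pool(volumes: list[SegVolume]) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(img, lab) for v in volumes for img, lab in zip(v.slices, v.labels)]


def _augment(img: np.ndarray, lab: np.ndarray, tc: TrainConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if tc.augment_flip and rng.random() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if tc.augment_flip and rng.random() < 0.5:
        img, lab = img[::-1, :], lab[::-1, :]
    if tc.augment_rotate and rng.random() < 0.5:
        angle = rng.uniform(-tc.rotate_degrees, tc.rotate_degrees)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    loss_log: list[dict]
    final_loss: float
    state_dict: dict


def train_model(model: SegModel, volumes: list[SegVolume], tc: TrainConfig,
                checkpoint_path=None, log_path=None) -> TrainResult:
    """SGD training on the slice pool of ``volumes``.

    Deterministic under a fixed ``tc.seed`` (sampling, augmentation and
    dropout all derive from seeded generators).  Raises
    :class:`TrainingDiverged` with a diagnostic if the loss goes
    non-finite.
    """
    pool = _slice_pool(volumes)
    if not pool:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(tc.seed)
    model.train()
    opt = nn.SGD(model.parameters(), lr=tc.lr, momentum=tc.momentum,
                 weight_decay=tc.weight_decay)
    log: list[dict] = []
    for it in range(tc.max_iterations):
        idx = rng.integers(0, len(pool), size=tc.batch_size)
        imgs, labs = [], []
        for i in idx:
            im, lb = _augment(pool[i][0], pool[i][1], tc, rng)
            imgs.append(im)
            labs.append(lb)
        batch = Tensor(np.stack(imgs)[:, None])
        labels = np.stack(labs).astype(np.int64)
        logits = model(batch)
        loss, ce, dl = combined_loss(logits, labels, tc)
        value = loss.item()
        if not math.isfinite(value):
            raise TrainingDiverged(
                f"non-finite loss at iteration {it}: total={value}, "
                f"ce={ce}, dice={dl}; consider lowering lr ({tc.lr})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % tc.log_every == 0 or it == tc.max_iterations - 1:
            log.append({"iteration": it, "loss": value, "ce": ce, "dice": dl})
    model.eval()
    result = TrainResult(loss_log=log, final_loss=log[-1]["loss"],
                         state_dict=model.state_dict())
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    if log_path is not None:
        Path(log_path).write_text("\n".join(json.dumps(r) for r in log))
    return result


# ---------------------------------------------------------------------------
# Checkpoints and inference
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path) -> None:
    state = model.state_dict()
    np.savez_compressed(path, __config__=np.array(model.cfg.to_yaml()), **state)


def load_checkpoint(path) -> SegModel:
    data = np.load(path, allow_pickle=False)
    cfg = NetworkConfig.from_yaml(str(data["__config__"]))
    model = build_model(cfg, init="zeros")
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model


def infer_volume(model: SegModel, volume: SegVolume) -> np.ndarray:
    """Per-slice forward + argmax, stacked to (S, H, W); deterministic."""
    if volume.slices.shape[-1] != model.cfg.image_size:
        raise ValueError(
            f"volume slices are {volume.slices.shape[-2:]}, model expects "
            f"{model.cfg.image_size}")
    return predict_volume(model, volume)


def training_dice(model: SegModel, volumes: list[SegVolume]) -> float:
    """Mean foreground Dice of the model's predictions on ``volumes``."""
    from .metrics import evaluate_volumes
    report = evaluate_volumes(model, volumes)
    return report.average["dsc"]


# ---------------------------------------------------------------------------
# Experiment grids
# ---------------------------------------------------------------------------

def run_experiment_grid(configs: list[NetworkConfig], train_volumes=None,
                        eval_volumes=None, tc: TrainConfig | None = None,
                        convention=None) -> list[dict]:
    """Accounting (always) and optional desk-scale train/eval per config.

    Per-variant failures are recorded in the row and the grid continues.
    """
    from .accounting import DEFAULT_CONVENTION, account
    conv = convention or DEFAULT_CONVENTION
    rows: list[dict] = []
    for cfg in configs:
        t = cfg.transformer
        row = {"variant": cfg.variant, "image_size": cfg.image_size,
               "branches": t.parallelism, "layers": t.depth,
               "dd_layers": t.dd_layers, "mlp_layers": t.mlp_layers}
        try:
            rep = account(cfg, conv)
            row["params_M"] = round(rep.params_millions, 2)
            row["flops_G"] = round(rep.flops_giga, 2)
            if train_volumes is not None:
                model = build_model(cfg, seed=tc.seed if tc else 0)
                result = train_model(model, train_volumes,
                                     tc or TrainConfig.desk_scale())
                row["final_loss"] = round(result.final_loss, 4)
                if eval_volumes is not None:
                    row["mean_dsc"] = round(
                        training_dice(model, eval_volumes), 4)
        except Exception as exc:   # noqa: BLE001 - grid must continue
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows
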