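"""Segmentation evaluation: DSC, HD95 and confusion-matrix metrics.

Metrics are computed per organ class on 3D volumes reconstructed from
2D slice predictions, following the multi-organ CT evaluation protocol:
slices are segmented independently, stacked into a volume per case, and
each foreground class is scored against the reference volume.  Reported
averages are over foreground classes (background excluded), averaging
each class over the cases in which it appears in the reference.

HD95 is the 95th-percentile symmetric surface distance in millimetres,
``max(d95(A->B), d95(B->A))`` — the form standard in this literature.
(The alternative ``d95(A->B) + d95(B->A)`` combination is available via
``combine="sum"`` for fidelity experiments.)  When either mask is empty
the distance is undefined; a NaN sentinel is returned and such records
are excluded from averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .networks import SegVolume, predict_volume

METRIC_NAMES = ("dsc", "hd95", "accuracy", "f1", "sensitivity", "precision")


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice_coefficient(pred_mask, true_mask) -> float:
    """Dice similarity 2|A.B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = _as_bool(pred_mask)
    b = _as_bool(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _surface_points(mask: np.ndarray, spacing, boundary_only: bool) -> np.ndarray:
    if boundary_only:
        eroded = ndimage.binary_erosion(mask)
        mask = mask & ~eroded
    pts = np.argwhere(mask).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def hausdorff95(pred_mask, true_mask, spacing=(1.0, 1.0, 1.0),
                percentile: float = 95.0, combine: str = "max",
                boundary_only: bool = False) -> float:
    """95th-percentile Hausdorff distance in physical units.

    Directed distances are computed over the full foreground voxel sets
    by default (``boundary_only=True`` restricts to the eroded boundary).
    Returns NaN when either mask is empty.
    """
    a = _as_bool(pred_mask)
    b = _as_bool(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != len(tuple(spacing)):
        raise ValueError("spacing rank must match mask rank")
    if not a.any() or not b.any():
        return math.nan
    pa = _surface_points(a, spacing, boundary_only)
    pb = _surface_points(b, spacing, boundary_only)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    q_ab = float(np.percentile(d_ab, percentile))
    q_ba = float(np.percentile(d_ba, percentile))
    if combine == "max":
        return max(q_ab, q_ba)
    if combine == "sum":
        return q_ab + q_ba
    raise ValueError(f"combine must be 'max' or 'sum', got {combine!r}")


def confusion_metrics(pred_mask, true_mask) -> dict[str, float]:
    """Accuracy, F1, sensitivity (recall) and precision from TP/TN/FP/FN.

    Ratios with zero denominator are reported as 0.0.
    """
    a = _as_bool(pred_mask)
    b = _as_bool(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    tn = int((~a & ~b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())

    def ratio(num, den):
        return num / den if den else 0.0

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "precision": ratio(tp, tp + fp),
    }


@dataclass
class MetricReport:
    """Per-class and foreground-averaged metrics over a case set."""

    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    average: dict[str, float] = field(default_factory=dict)
    per_case: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"per_class": {int(k): v for k, v in self.per_class.items()},
                "average": self.average}


def score_volume(pred_labels: np.ndarray, true_labels: np.ndarray,
                 spacing=(1.0, 1.0, 1.0), n_classes: int | None = None,
                 ) -> dict[int, dict[str, float]]:
    """All six metrics for every foreground class of one volume pair.

    Classes absent from the reference are skipped.  HD95 is NaN when the
    prediction for a present class is empty.
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("prediction/reference shapes differ")
    if n_classes is None:
        n_classes = int(max(pred_labels.max(), true_labels.max())) + 1
    out: dict[int, dict[str, float]] = {}
    for cls in range(1, n_classes):
        t = true_labels == cls
        if not t.any():
            continue
        p = pred_labels == cls
        rec = {"dsc": dice_coefficient(p, t),
               "hd95": hausdorff95(p, t, spacing)}
        rec.update(confusion_metrics(p, t))
        out[cls] = rec
    return out


def aggregate(case_scores: list[dict[int, dict[str, float]]]) -> MetricReport:
    """Average per-class over cases (NaN-excluded), then over classes."""
    report = MetricReport()
    classes = sorted({c for s in case_scores for c in s})
    for cls in classes:
        vals = {m: [] for m in METRIC_NAMES}
        for s in case_scores:
            if cls in s:
                for m in METRIC_NAMES:
                    vals[m].append(s[cls][m])
        report.per_class[cls] = {
            m: (float(np.nanmean(v)) if np.isfinite(v).any() else math.nan)
            for m, v in ((m, np.asarray(vals[m])) for m in METRIC_NAMES)}
    if classes:
        report.average = {
            m: float(np.nanmean([report.per_class[c][m] for c in classes]))
            for m in METRIC_NAMES}
    return report


def evaluate_volumes(model, volumes: list[SegVolume],
                     n_classes: int | None = None) -> MetricReport:
    """Slice-wise inference, 3D reconstruction, per-organ scoring.

    Each case is segmented slice by slice with the model in evaluation
    mode, the slices are stacked back into a volume, and the six metrics
    are computed per present organ class, then averaged over cases and
    over foreground classes.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    if n_classes is None:
        n_classes = model.cfg.n_classes
    report_scores = []
    per_case = []
    for vol in volumes:
        pred = predict_volume(model, vol)
        scores = score_volume(pred, vol.labels, vol.spacing, n_classes)
        report_scores.append(scores)
        per_case.append({"case_id": vol.case_id,
                         "scores": {int(k): v for k, v in scores.items()}})
    report = aggregate(report_scores)
    report.per_case = per_case
    return report
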