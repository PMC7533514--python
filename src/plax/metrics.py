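"""Evaluation metrics for segmentation maps and keypoint predictions.

The segmentation metrics are the standard trio used to score dense
prediction against a ground-truth label map: pixel accuracy, mean
per-class accuracy, and mean intersection-over-union, all derived from a
single k x k confusion matrix ``C`` whose entry ``C[i, j]`` counts pixels
of true class ``i`` predicted as class ``j``.  Keypoint predictions are
scored with PCK (percentage of correct keypoints): the fraction of
predictions falling strictly within a radius ``x * d`` of the truth,
where ``d`` is a per-item normalizer (here, the disc diameter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "KeypointEval",
    "confusion",
    "pixel_accuracy",
    "mean_class_accuracy",
    "mean_iou",
    "per_class_iou",
    "pck",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel-level confusion counts between two label maps.

    ``counts[i, j]`` is the number of pixels whose ground truth is class
    ``i`` and whose prediction is class ``j``; ``row_totals[i]`` is the
    ground-truth pixel count ``T_i`` of class ``i``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


def confusion(pred: np.ndarray, truth: np.ndarray, k: int) -> ConfusionMatrix:
    """Count pixels of each (truth class, predicted class) pair.

    Parameters
    ----------
    pred, truth
        Integer label maps of identical shape with values in ``[0, k)``.
    k
        Number of classes.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.size and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{name} contains labels outside [0, {k})")
    idx = truth.ravel().astype(np.int64) * k + pred.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of pixels whose predicted class equals the truth."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def _present_classes(cm: ConfusionMatrix) -> np.ndarray:
    """Classes with any ground-truth or predicted pixels.

    Classes absent from both maps are dropped from class-averaged metrics
    to avoid 0/0 on small crops.
    """
    present = (cm.row_totals > 0) | (cm.counts.sum(axis=0) > 0)
    return np.flatnonzero(present)


def mean_class_accuracy(cm: ConfusionMatrix) -> float:
    """Mean over classes of the per-class recall ``C_ii / T_i``."""
    rows = cm.row_totals
    keep = _present_classes(cm)
    keep = keep[rows[keep] > 0]
    if keep.size == 0:
        raise ValueError("no class has ground-truth pixels")
    diag = np.diag(cm.counts)
    return float(np.mean(diag[keep] / rows[keep]))


def per_class_iou(cm: ConfusionMatrix, variant: str = "standard") -> np.ndarray:
    """Per-class intersection-over-union for the classes present.

    ``variant='standard'`` uses TP / (TP + FN + FP).  ``variant='as_printed'``
    instead repeats the row (false-negative) sum in the denominator,
    TP / (T_i + sum_{j != i} C_ij); this reading double-counts the
    false negatives and is kept only for comparison (see
    :func:`mean_iou`).  Returns an array aligned with
    ``_present_classes``; absent classes are excluded.
    """
    keep = _present_classes(cm)
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals.astype(float)
    if variant == "standard":
        fp = cm.counts.sum(axis=0) - np.diag(cm.counts)
        denom = rows + fp
    elif variant == "as_printed":
        fn = rows - diag
        denom = rows + fn
    else:
        raise ValueError(f"unknown iou variant: {variant!r}")
    with np.errstate(invalid="ignore"):
        iou = np.where(denom > 0, diag / np.maximum(denom, 1), 0.0)
    return iou[keep]


def mean_iou(cm: ConfusionMatrix, variant: str = "standard") -> float:
    """Mean IoU over classes present in truth or prediction."""
    iou = per_class_iou(cm, variant=variant)
    if iou.size == 0:
        raise ValueError("empty confusion matrix")
    return float(iou.mean())


@dataclass
class KeypointEval:
    """Paired keypoint truths/predictions with per-item normalizers.

    ``normalizers[i]`` is the length scale (disc diameter, px) used to
    normalize the i-th localization error; ``grid`` is the list of
    normalized distances at which the PCK curve is evaluated.
    """

    truths: Sequence[tuple[float, float]]
    predictions: Sequence[tuple[float, float]]
    normalizers: Sequence[float]
    grid: Sequence[float] = field(default_factory=lambda: list(np.linspace(0, 1, 21)))

    def __post_init__(self) -> None:
        if not (len(self.truths) == len(self.predictions) == len(self.normalizers)):
            raise ValueError("truths, predictions and normalizers must have equal length")
        if any(d <= 0 for d in self.normalizers):
            raise ValueError("normalizers must be positive")
        g = list(self.grid)
        if any(b < a for a, b in zip(g, g[1:])) or (g and (g[0] < 0 or g[-1] > 1)):
            raise ValueError("grid must be sorted within [0, 1]")


def pck(ev: KeypointEval) -> list[tuple[float, float]]:
    """PCK curve: fraction of predictions with error strictly below x*d.

    The inequality is strict, so PCK@0 is exactly 0 even for perfect
    predictions.
    """
    t = np.asarray(ev.truths, dtype=float)
    p = np.asarray(ev.predictions, dtype=float)
    d = np.asarray(ev.normalizers, dtype=float)
    err = np.linalg.norm(p - t, axis=1) / d
    return [(float(x), float(np.mean(err < x))) for x in ev.grid]


def metrics_report(cm: ConfusionMatrix, keypoints: KeypointEval | None = None,
                   iou_variant: str = "standard") -> dict:
    """Bundle the metric suite into a JSON-serializable report."""
    report = {
        "pixel_acc": pixel_accuracy(cm),
        "class_acc": mean_class_accuracy(cm),
        "mean_iou": mean_iou(cm, variant=iou_variant),
        "per_class_iou": [float(v) for v in per_class_iou(cm, variant=iou_variant)],
    }
    if keypoints is not None:
        report["pck"] = [[x, f] for x, f in pck(keypoints)]
    return report


def write_metrics_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
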