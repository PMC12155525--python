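"""2D segmentation metrics: per-class IoU, accuracy, precision.

IoU for class ``c`` is ``|pred==c AND truth==c| / |pred==c OR truth==c|``
summed over image pixels.  The mean IoU of an image averages over the
classes present in the ground truth or the prediction — classes absent
from both are excluded rather than counted as perfect.  Dataset-level
scores are the average of per-image means (not pooled pixels), which
gives every image pair the same weight regardless of its class areas.
The adult-teeth mean IoU restricts the average to permanent tooth
classes, excluding third molars, primary teeth, rugae and background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import LabelScheme, default_label_scheme

__all__ = ["Metrics2D", "dataset_metrics", "metrics_2d"]


@dataclass
class Metrics2D:
    per_class_iou: dict[int, float]
    pixel_accuracy: float
    precision: float  # macro average of per-class precision
    mean_iou: float
    adult_teeth_mean_iou: float


def metrics_2d(
    pred: np.ndarray, truth: np.ndarray, scheme: LabelScheme | None = None
) -> Metrics2D:
    """Score one predicted label image against its ground truth.

    Both images are integer class-id arrays of the same shape (decode
    palette-colored images with ``scheme.decode_colors`` first).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"image sizes differ: {pred.shape} vs {truth.shape}")
    scheme = scheme or default_label_scheme()
    present = np.union1d(np.unique(pred), np.unique(truth))
    per_class: dict[int, float] = {}
    precisions = []
    for c in present:
        p = pred == c
        t = truth == c
        inter = int(np.logical_and(p, t).sum())
        union = int(np.logical_or(p, t).sum())
        per_class[int(c)] = inter / union
        if p.any():
            precisions.append(inter / int(p.sum()))
    adult = [v for c, v in per_class.items() if c in scheme.adult_tooth_ids]
    return Metrics2D(
        per_class_iou=per_class,
        pixel_accuracy=float((pred == truth).mean()),
        precision=float(np.mean(precisions)) if precisions else float("nan"),
        mean_iou=float(np.mean(list(per_class.values()))),
        adult_teeth_mean_iou=float(np.mean(adult)) if adult else float("nan"),
    )


def dataset_metrics(image_pairs, scheme: LabelScheme | None = None) -> Metrics2D:
    """Average per-image metrics over (pred, truth) pairs.

    Every aggregate is the mean of the per-image value (average of
    means); per-class IoUs are averaged over the images in which the
    class is present in prediction or truth.
    """
    pairs = list(image_pairs)
    if not pairs:
        raise ValueError("empty test set")
    scheme = scheme or default_label_scheme()
    per_image = [metrics_2d(p, t, scheme) for p, t in pairs]
    class_acc: dict[int, list[float]] = {}
    for m in per_image:
        for c, v in m.per_class_iou.items():
            class_acc.setdefault(c, []).append(v)
    return Metrics2D(
        per_class_iou={c: float(np.mean(v)) for c, v in sorted(class_acc.items())},
        pixel_accuracy=float(np.mean([m.pixel_accuracy for m in per_image])),
        precision=float(np.mean([m.precision for m in per_image])),
        mean_iou=float(np.mean([m.mean_iou for m in per_image])),
        adult_teeth_mean_iou=float(np.nanmean(
            [m.adult_teeth_mean_iou for m in per_image]
        )),
    )
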