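"""Segmentation and classification evaluation.

Segmentation metrics (Dice, IoU, pixel accuracy) are computed per mask pair
and averaged unweighted over images; the empty/empty case scores 1.0 (two
empty masks agree perfectly).  Classification metrics are derived from a
truth-by-prediction confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels with matching labels (foreground + background)."""
    a, b = _check_pair(pred, truth)
    return float((a == b).mean())


def mean_iou(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Unweighted mean of foreground IoU over (pred, truth) mask pairs."""
    if not pairs:
        raise ValueError("no mask pairs given")
    return float(np.mean([iou(p, t) for p, t in pairs]))


def segmentation_report(pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict[str, float]:
    """Per-image-averaged Dice / IoU / pixel accuracy over mask pairs."""
    if not pairs:
        raise ValueError("no mask pairs given")
    return {
        "mean_dice": float(np.mean([dice(p, t) for p, t in pairs])),
        "mean_iou": mean_iou(pairs),
        "pixel_accuracy": float(np.mean([pixel_accuracy(p, t) for p, t in pairs])),
    }


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = prediction) plus derived rates."""

    classes: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "zero_division_flags": self.zero_division_flags,
        }


def classification_report(truths, preds, classes: list[str] | None = None) -> EvalReport:
    """Build an :class:`EvalReport` from parallel truth/prediction labels.

    Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
    mean, accuracy = (TP+TN)/total.  A zero denominator yields 0.0 and the
    affected ``class:metric`` is recorded in ``zero_division_flags``.
    """
    truths = [getattr(t, "value", t) for t in truths]
    preds = [getattr(p, "value", p) for p in preds]
    if len(truths) != len(preds):
        raise ValueError(f"length mismatch: {len(truths)} truths vs {len(preds)} preds")
    if classes is None:
        classes = sorted(set(truths) | set(preds))
    unknown = (set(truths) | set(preds)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    cm = _sk_confusion(truths, preds, labels=classes)
    total = cm.sum()
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn

        def rate(num, den, metric):
            if den == 0:
                flags.append(f"{cls}:{metric}")
                return 0.0
            return float(num / den)

        precision = rate(tp, tp + fp, "precision")
        recall = rate(tp, tp + fn, "recall")
        f1 = rate(2 * precision * recall, precision + recall, "f1")
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "accuracy": float((tp + tn) / total) if total else 0.0,
        }
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return EvalReport(list(classes), cm, per_class, accuracy, flags)
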