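"""Training objectives and segmentation-quality metrics.

The segmentation loss is the soft Dice loss

    L_dice = 1 - (2 * sum(p*g) + eps) / (sum(p) + sum(g) + eps)

summed over every voxel of the batch, with ``eps`` a small smoothing
constant that keeps the ratio defined when both prediction and reference
are empty.  Aggregating all voxels of the foreground class makes the loss
insensitive to the overwhelming background fraction of tumour volumes.

The auxiliary lesion-present classifier is trained with cross-entropy
``L_ce = -sum(g * log p)`` over the class probabilities of each volume,
and the multi-task objective is ``L = L_dice + lambda * L_ce``.

Evaluation uses voxel confusion counts: ``IoU = TP / (TP + FN + FP)`` and
``DSC = 2*TP / (2*TP + FN + FP)``, related by ``DSC = 2*IoU / (1 + IoU)``.
Both are defined as 1 when prediction and reference are both empty.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOG_FLOOR = 1e-12  # clamp for log p at a true class


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class LossValue:
    dice: float
    ce: float
    ce_weight: float

    @property
    def combined(self) -> float:
        return self.dice + self.ce_weight * self.ce


def dice_loss(probs: np.ndarray, labels: np.ndarray,
              epsilon: float = 1e-6) -> float:
    """Soft Dice loss over all voxels; 0 for a perfect hard prediction."""
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = np.asarray(probs, dtype=np.float64)
    g = np.asarray(labels, dtype=np.float64)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def dice_loss_grad(probs: np.ndarray, labels: np.ndarray,
                   epsilon: float = 1e-6) -> np.ndarray:
    """d L_dice / d p, used by the training loop."""
    p = np.asarray(probs, dtype=np.float64)
    g = np.asarray(labels, dtype=np.float64)
    inter = (p * g).sum()
    denom = p.sum() + g.sum() + epsilon
    num = 2.0 * inter + epsilon
    grad = -(2.0 * g * denom - num) / denom ** 2
    return grad.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(cls_probs: np.ndarray, cls_labels: np.ndarray) -> float:
    """Mean ``-sum(g * log p)`` over the batch; inputs are probabilities."""
    p = np.atleast_2d(np.asarray(cls_probs, dtype=np.float64))
    g = np.atleast_2d(np.asarray(cls_labels, dtype=np.float64))
    if p.shape != g.shape:
        raise ValueError("probability/label shape mismatch")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("each probability vector must sum to 1")
    return float(-(g * np.log(np.clip(p, LOG_FLOOR, 1.0))).sum(axis=-1).mean())


def cross_entropy_from_logits(logits: np.ndarray, label: int) -> tuple[float, np.ndarray]:
    """Loss and d L / d logits for one volume (softmax + CE fused)."""
    p = softmax(logits)
    g = np.zeros_like(p)
    g[..., label] = 1.0
    loss = float(-(g * np.log(np.clip(p, LOG_FLOOR, 1.0))).sum())
    return loss, (p - g).astype(np.float32)


def combined_loss(dice: float, ce: float | None = None,
                  ce_weight: float = 1.0) -> LossValue:
    """Multi-task objective ``dice + lambda * ce``; lambda=0 is pure Dice."""
    return LossValue(dice=float(dice), ce=float(ce or 0.0), ce_weight=float(ce_weight))


def confusion_counts(pred: np.ndarray, label: np.ndarray) -> ConfusionCounts:
    """Exact voxel tallies of a binary prediction against a binary reference."""
    p = np.asarray(pred)
    g = np.asarray(label)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    for a, name in ((p, "pred"), (g, "label")):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    p = p.astype(bool)
    g = g.astype(bool)
    return ConfusionCounts(tp=int((p & g).sum()), fp=int((p & ~g).sum()),
                           fn=int((~p & g).sum()), tn=int((~p & ~g).sum()))


def iou(counts: ConfusionCounts) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    union = counts.tp + counts.fn + counts.fp
    if union == 0:
        return 1.0
    return counts.tp / union


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Per-volume metrics plus a trailing mean row."""
    df = pd.DataFrame(rows)
    if len(df):
        mean = df.drop(columns="sample_id").mean(numeric_only=True)
        mean["sample_id"] = "mean"
        df = pd.concat([df, mean.to_frame().T], ignore_index=True)
    return df
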