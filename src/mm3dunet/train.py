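"""Preprocessing, augmentation, slab sampling and the optimisation loop.

The recipe: z-score intensity normalisation; random volumetric augmentation
(in-plane rotation up to +/-15 degrees, horizontal flip with probability
0.5, +/-20 % linear intensity scaling); training on contiguous slabs of 16
or 32 axial slices drawn uniformly from each volume; an 8:2 train/test
split; Adam (first-moment decay 0.95, decoupled weight decay 1e-4) with a
single-cycle cosine-annealed learning rate starting at 1e-4:

    lr_t = lr_0 / 2 * (1 + cos(t * pi / T))

with T the number of epochs.  A small validation subset is carved from the
training split for curve monitoring.  Everything is driven by one seed, so
identical configurations reproduce identical histories bit for bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .io_synth import VolumeSample
from .losses_metrics import (combined_loss, confusion_counts, cross_entropy_from_logits,
                             dice_loss, dice_loss_grad, dsc, iou)
from .network import MMNet, predict_mask


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 130
    batch_size: int = 24
    lr0: float = 1e-4
    weight_decay: float = 1e-4
    beta1: float = 0.95
    slab_depth: int = 16
    split_ratio: float = 0.8
    val_fraction: float = 0.1
    ce_weight: float = 1.0
    dice_epsilon: float = 1e-6
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr0 <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if not 0 < self.beta1 < 1:
            raise ValueError("beta1 must lie in (0, 1)")
        if self.slab_depth not in (16, 32):
            raise ValueError("slab_depth must be 16 or 32")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class AugmentParams:
    max_rotation_deg: float = 15.0
    flip_probability: float = 0.5
    intensity_scale_range: float = 0.20

    def __post_init__(self):
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip probability must lie in [0, 1]")
        if self.max_rotation_deg < 0 or self.intensity_scale_range < 0:
            raise ValueError("augmentation magnitudes must be non-negative")


def cosine_lr(step: int, total: int, lr0: float) -> float:
    """Single-cycle cosine annealing: lr0 at step 0, zero at step T."""
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    return lr0 / 2.0 * (1.0 + math.cos(step * math.pi / total))


def zscore_normalize(volume: np.ndarray) -> np.ndarray:
    """Standardise to zero mean, unit standard deviation."""
    v = np.asarray(volume, dtype=np.float32)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant volume (zero variance)")
    return (v - v.mean()) / sd


def augment(sample: VolumeSample, params: AugmentParams,
            rng: np.random.Generator) -> VolumeSample:
    """Random in-plane rotation, horizontal flip, and intensity scaling.

    The identical spatial transform is applied to volume (linear
    interpolation) and mask (nearest neighbour); intensity scaling touches
    the volume only.  All draws come from ``rng`` in a fixed order.
    """
    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
    do_flip = rng.random() < params.flip_probability
    scale = 1.0 + rng.uniform(-params.intensity_scale_range,
                              params.intensity_scale_range)
    vol = sample.volume
    mask = sample.mask
    if angle != 0.0:
        vol = ndimage.rotate(vol, angle, axes=(1, 2), reshape=False,
                             order=1, mode="nearest")
        mask = ndimage.rotate(mask, angle, axes=(1, 2), reshape=False,
                              order=0, mode="constant")
    if do_flip:
        vol = vol[:, :, ::-1]
        mask = mask[:, :, ::-1]
    vol = vol * scale
    mask = np.ascontiguousarray(mask).astype(np.uint8)
    return VolumeSample(volume=np.ascontiguousarray(vol), mask=mask,
                        has_lesion=bool(mask.any()), sample_id=sample.sample_id,
                        voxel_spacing=sample.voxel_spacing)


def sample_slab(sample: VolumeSample, slab_depth: int,
                rng: np.random.Generator) -> VolumeSample:
    """Crop a contiguous window of ``slab_depth`` axial slices, uniform start."""
    depth = sample.volume.shape[0]
    if depth < slab_depth:
        raise ValueError(f"volume depth {depth} < slab depth {slab_depth}")
    start = int(rng.integers(0, depth - slab_depth + 1))
    vol = sample.volume[start:start + slab_depth]
    mask = sample.mask[start:start + slab_depth]
    return VolumeSample(volume=vol, mask=mask, has_lesion=bool(mask.any()),
                        sample_id=sample.sample_id,
                        voxel_spacing=sample.voxel_spacing)


def split_dataset(manifest: list[str], ratio: float, seed: int) -> tuple[list[str], list[str]]:
    """Deterministic shuffled split at floor(ratio * n); disjoint, exhaustive."""
    if not manifest:
        raise ValueError("empty manifest")
    order = np.random.default_rng(seed).permutation(len(manifest))
    cut = int(math.floor(ratio * len(manifest)))
    ids = [manifest[i] for i in order]
    return ids[:cut], ids[cut:]


def _forward_losses(network: MMNet, sample: VolumeSample, config: TrainConfig):
    """One training example: forward, losses, and gradient accumulation."""
    x = sample.volume[None]  # add channel axis
    out = network.forward(x)
    labels = sample.mask[None].astype(np.float32)
    d = dice_loss(out.seg_probs, labels, config.dice_epsilon)
    seg_grad = dice_loss_grad(out.seg_probs, labels, config.dice_epsilon)
    ce = None
    cls_grad = None
    if network.config.use_act and config.ce_weight > 0:
        ce, g = cross_entropy_from_logits(out.cls_logits, int(sample.has_lesion))
        cls_grad = config.ce_weight * g
    network.backward(seg_grad.astype(np.float32), cls_grad)
    return combined_loss(d, ce, config.ce_weight)


def train_model(network: MMNet, dataset: list[VolumeSample], config: TrainConfig,
                augment_params: AugmentParams | None = AugmentParams()) -> pd.DataFrame:
    """Optimise the network; returns the per-epoch history table.

    Columns: epoch, lr, dice, ce, combined, val_iou, val_dsc.  The
    validation subset (``val_fraction`` of the provided samples, at least
    one) is held fixed across epochs and excluded from optimisation.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.val_fraction * len(dataset)))) \
        if len(dataset) > 1 else 0
    order = rng.permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]
    params = network.parameters()
    opt = nn.Adam(params, lr=config.lr0, beta1=config.beta1,
                  weight_decay=config.weight_decay)
    history = []
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr0)
        opt.lr = lr
        epoch_losses = []
        idx = rng.permutation(len(train_set))
        pending = 0
        for j, i in enumerate(idx):
            sample = train_set[i]
            if augment_params is not None:
                sample = augment(sample, augment_params, rng)
            sample = replace(sample, volume=zscore_normalize(sample.volume))
            slab = sample_slab(sample, config.slab_depth, rng)
            loss = _forward_losses(network, slab, config)
            if not math.isfinite(loss.combined):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.combined}")
            epoch_losses.append(loss)
            pending += 1
            if pending == config.batch_size or j == len(idx) - 1:
                for p in params.values():
                    p.grad /= pending
                opt.step()
                network.zero_grad()
                pending = 0
        val_iou = val_dsc = float("nan")
        if val_set:
            vt = evaluate_model(network, val_set, config.threshold)
            mean = vt[vt["sample_id"] == "mean"]
            val_iou = float(mean["iou"].iloc[0])
            val_dsc = float(mean["dsc"].iloc[0])
        history.append({
            "epoch": epoch,
            "lr": lr,
            "dice": float(np.mean([l.dice for l in epoch_losses])),
            "ce": float(np.mean([l.ce for l in epoch_losses])),
            "combined": float(np.mean([l.combined for l in epoch_losses])),
            "val_iou": val_iou,
            "val_dsc": val_dsc,
        })
    return pd.DataFrame(history)


def evaluate_model(network: MMNet, dataset: list[VolumeSample],
                   threshold: float = 0.5) -> pd.DataFrame:
    """Volume-wise IoU / DSC (and classifier accuracy when present).

    Deterministic; volumes are z-scored exactly as during training.
    """
    rows = []
    for sample in dataset:
        x = zscore_normalize(sample.volume)[None]
        out = network.forward(x)
        pred = predict_mask(out, threshold)[0]
        counts = confusion_counts(pred, sample.mask)
        row = {"sample_id": sample.sample_id, "iou": iou(counts), "dsc": dsc(counts)}
        if out.cls_logits is not None:
            row["cls_correct"] = float(int(np.argmax(out.cls_logits))
                                       == int(sample.has_lesion))
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.drop(columns="sample_id").mean(numeric_only=True)
    mean["sample_id"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)
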