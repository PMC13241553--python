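"""Soft Dice losses, boundary weighting, and deep supervision."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .autodiff import Tensor

__all__ = ["one_hot", "downsample_labels", "dice_loss",
           "boundary_weight_map", "boundary_weighted_dice_loss",
           "deep_supervision_loss", "cross_entropy_loss", "combined_loss",
           "SMOOTH_EPS"]

SMOOTH_EPS = 1e-5


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(num_classes, D, H, W) one-hot encoding of an integer label map."""
    out = np.zeros((num_classes,) + labels.shape, dtype=np.float32)
    for c in range(num_classes):
        out[c] = labels == c
    return out


def downsample_labels(labels: np.ndarray, factor: int = 2) -> np.ndarray:
    """Nearest-neighbor downsampling of an integer label map."""
    return labels[::factor, ::factor, ::factor]


def _soft_dice(probs: Tensor, target: np.ndarray,
               weights: Optional[np.ndarray],
               class_weights: Optional[np.ndarray],
               eps: float, include_background: bool = False) -> Tensor:
    """1 - mean over (foreground) classes of (voxel-weighted) soft Dice."""
    p = probs.data
    if p.shape != target.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {target.shape}")
    sums = p.sum(axis=0)
    if np.abs(sums - 1.0).max() > 1e-3:
        raise ValueError("predictions are not normalized over the class axis")
    w = np.ones(p.shape[1:], dtype=np.float32) if weights is None \
        else np.asarray(weights, dtype=np.float32)
    if w.shape != p.shape[1:]:
        raise ValueError(f"weight shape {w.shape} != spatial shape {p.shape[1:]}")

    c0 = 0 if include_background else 1
    ncls = p.shape[0] - c0
    cw = np.ones(ncls) if class_weights is None else np.asarray(class_weights,
                                                                dtype=float)
    cw = cw / cw.sum()
    wp = w[None] * p[c0:]
    wt = w[None] * target[c0:]
    num = 2.0 * (wp * target[c0:]).sum(axis=(1, 2, 3)) + eps
    den = wp.sum(axis=(1, 2, 3)) + wt.sum(axis=(1, 2, 3)) + eps
    loss_val = float(1.0 - (cw * num / den).sum())

    def backward(g: np.ndarray) -> None:
        if probs.requires_grad:
            gp = np.zeros_like(p)
            # d dice_c / d p_{c,v} = w_v (2 t_{c,v} den_c - num_c) / den_c^2
            coef = (cw / den ** 2)[:, None, None, None]
            gp[c0:] = -coef * w[None] * (
                2.0 * target[c0:] * den[:, None, None, None]
                - num[:, None, None, None])
            probs.accumulate(float(g) * gp)

    return Tensor(loss_val, (probs,), backward)


def dice_loss(probs: Tensor, target_onehot: np.ndarray,
              class_weights: Optional[np.ndarray] = None,
              eps: float = SMOOTH_EPS) -> Tensor:
    """Soft Dice loss averaged over foreground classes.

    Zero (up to the smoothing term) iff the prediction equals the
    one-hot target exactly.
    """
    return _soft_dice(probs, target_onehot, None, class_weights, eps)


def boundary_weight_map(labels: np.ndarray, w_max: float = 5.0,
                        tau: float = 2.0) -> np.ndarray:
    """Per-voxel loss weights emphasizing label boundaries.

    w(v) = 1 + (w_max - 1) * exp(-d(v)/tau), with d(v) the Euclidean
    distance in voxels to the nearest boundary voxel; a boundary voxel is
    one with a differently-labeled 6-neighbor.
    """
    if w_max < 1:
        raise ValueError("w_max must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    labels = np.asarray(labels)
    boundary = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        diff = np.diff(labels, axis=axis) != 0
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        boundary[tuple(lo)] |= diff
        boundary[tuple(hi)] |= diff
    if not boundary.any():
        return np.ones(labels.shape, dtype=np.float32)
    d = ndimage.distance_transform_edt(~boundary)
    return (1.0 + (w_max - 1.0) * np.exp(-d / tau)).astype(np.float32)


def boundary_weighted_dice_loss(probs: Tensor, target_onehot: np.ndarray,
                                weights: np.ndarray,
                                class_weights: Optional[np.ndarray] = None,
                                eps: float = SMOOTH_EPS) -> Tensor:
    """Soft Dice with voxel weights; reduces to dice_loss when w == 1."""
    return _soft_dice(probs, target_onehot, weights, class_weights, eps)


def cross_entropy_loss(probs: Tensor, target_onehot: np.ndarray,
                       fg_weight: float = 1.0, eps: float = 1e-7) -> Tensor:
    """Mean voxel-wise negative log-likelihood of the true class.

    ``fg_weight`` up-weights foreground voxels (weights renormalized to
    mean 1) to counter the extreme class imbalance of thin structures.
    Used as a stabilizing companion to the Dice terms during training
    (a routine training-detail choice).
    """
    p = probs.data
    n = float(np.prod(p.shape[1:]))
    wv = 1.0 + (fg_weight - 1.0) * (target_onehot[0] == 0)
    wv = (wv / wv.mean()).astype(np.float32)
    pt = (p * target_onehot).sum(axis=0)
    loss_val = float(-(wv * np.log(pt + eps)).mean())

    def backward(g: np.ndarray) -> None:
        if probs.requires_grad:
            probs.accumulate(float(g) * (-target_onehot
                                         * (wv / (pt + eps))[None] / n))

    return Tensor(loss_val, (probs,), backward)


def combined_loss(probs: Tensor, target_onehot: np.ndarray,
                  weights: Optional[np.ndarray] = None,
                  ce_weight: float = 0.5, ce_fg_weight: float = 10.0,
                  include_background: bool = True) -> Tensor:
    """Soft Dice (optionally boundary-weighted) plus weighted cross-entropy.

    The Dice mean includes the background class here: without it a
    randomly initialized network has no incentive to ever predict
    background and saturates to all-foreground.
    """
    d = _soft_dice(probs, target_onehot, weights, None, SMOOTH_EPS,
                   include_background=include_background)
    if ce_weight == 0:
        return d
    ce = cross_entropy_loss(probs, target_onehot, fg_weight=ce_fg_weight)
    total = d.data + ce_weight * ce.data

    def backward(g: np.ndarray) -> None:
        d.accumulate(g)
        ce.accumulate(ce_weight * g)

    return Tensor(total, (d, ce), backward)


def deep_supervision_loss(main_loss: Tensor, aux_loss: Optional[Tensor],
                          aux_weight: float) -> Tensor:
    """Total = main + aux_weight * aux; aux_weight = 0 recovers main."""
    if aux_loss is None or aux_weight == 0:
        return main_loss
    total = main_loss.data + aux_weight * aux_loss.data

    def backward(g: np.ndarray) -> None:
        main_loss.accumulate(g)
        aux_loss.accumulate(aux_weight * g)

    return Tensor(total, (main_loss, aux_loss), backward)
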