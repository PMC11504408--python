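"""Segmentation training losses: BCE, soft Dice, Smooth L1 and their hybrid.

All functions accept either a :class:`SegmentationPair` or an explicit
``(pred, gt)`` pair; predictions may be autograd tensors (for training) or
plain arrays.  Ground truth must be strictly binary.

The hybrid loss is ``dice + bce + 0.5 * smooth_l1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, where_scalar

__all__ = [
    "SegmentationPair",
    "bce_loss",
    "dice_loss",
    "smooth_l1_loss",
    "hybrid_loss",
    "BCE_EPS",
    "DICE_SMOOTH",
]

BCE_EPS = 1e-7
DICE_SMOOTH = 1.0


@dataclass
class SegmentationPair:
    """Predicted probability map and binary ground truth of equal shape."""

    pred: Tensor
    gt: np.ndarray

    def __post_init__(self):
        self.pred = as_tensor(self.pred)
        self.gt = np.asarray(self.gt)
        if self.pred.shape != self.gt.shape:
            raise ValueError(f"shape mismatch: pred {self.pred.shape} vs gt {self.gt.shape}")
        vals = np.unique(self.gt)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("ground truth must be binary (values in {0, 1})")

    @property
    def n_pixels(self) -> int:
        return int(self.pred.size)


def _unpack(pair_or_pred, gt) -> SegmentationPair:
    if isinstance(pair_or_pred, SegmentationPair):
        return pair_or_pred
    return SegmentationPair(pair_or_pred, gt)


def bce_loss(pair_or_pred, gt=None) -> Tensor:
    """Mean binary cross-entropy, with predictions clamped to
    ``[eps, 1 - eps]`` (eps = 1e-7) for numerical safety."""
    pair = _unpack(pair_or_pred, gt)
    p = pair.pred.clip(BCE_EPS, 1.0 - BCE_EPS)
    g = pair.gt.astype(np.float64 if p.dtype == np.float64 else np.float32)
    nll = -(g * p.log() + (1.0 - g) * (1.0 - p).log())
    return nll.mean()


def dice_loss(pair_or_pred, gt=None, smooth: float = DICE_SMOOTH) -> Tensor:
    """Soft Dice loss ``1 - (2|X∩Y| + s) / (|X| + |Y| + s)``.

    The smoothing constant ``s`` (default 1) guards the empty-mask 0/0
    case; pass ``smooth=0`` for the unsmoothed ratio.
    """
    pair = _unpack(pair_or_pred, gt)
    p = pair.pred
    g = pair.gt.astype(np.float32)
    inter = (p * g).sum()
    total = p.sum() + float(g.sum())
    return 1.0 - (2.0 * inter + smooth) / (total + smooth)


def smooth_l1_loss(pair_or_pred, gt=None, foreground_only: bool = True) -> Tensor:
    """Piecewise quadratic/linear loss on the per-pixel error ``d = |p - g|``:
    ``0.5 d^2`` for ``d < 1`` and ``d - 0.5`` otherwise (continuous at 1).

    By default the mean is taken over ground-truth foreground pixels (the
    nodule region), falling back to all pixels when the mask is empty;
    ``foreground_only=False`` always averages over every pixel.
    """
    pair = _unpack(pair_or_pred, gt)
    p = pair.pred
    g = pair.gt.astype(np.float32)
    d = (p - g).abs()
    small = d.data < 1.0
    per_pixel = where_scalar(small, 0.5 * d * d, d - 0.5)
    if foreground_only and pair.gt.sum() > 0:
        fg = pair.gt.astype(bool)
        return (per_pixel * fg).sum() * (1.0 / float(fg.sum()))
    return per_pixel.mean()


def hybrid_loss(pair_or_pred, gt=None, smooth: float = DICE_SMOOTH,
                foreground_only: bool = True) -> Tensor:
    """``dice + bce + 0.5 * smooth_l1`` on the same prediction/target pair."""
    pair = _unpack(pair_or_pred, gt)
    return (dice_loss(pair, smooth=smooth)
            + bce_loss(pair)
            + 0.5 * smooth_l1_loss(pair, foreground_only=foreground_only))
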