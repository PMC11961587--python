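"""Compound cross-entropy + Dice objective with four-branch deep supervision.

The per-branch objective is ``0.3 * CE + 0.7 * soft-Dice``; the total
training loss weights the full-resolution branch and the three
auxiliary branches (strides 8/16/32, bilinearly upsampled to full
resolution before scoring) as 0.7 / 0.1 / 0.1 / 0.1.  The Dice term is
the smoothed probabilistic form, averaged over classes and batch; with
crisp inputs and vanishing smoothing it reduces to the set formula
``1 - 2|P∩G| / (|P|+|G|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, resize_bilinear
from .decoder import LogitsBundle
from .exceptions import ConfigurationError, ShapeError

__all__ = ["LossConfig", "one_hot", "dice_loss", "cross_entropy",
           "combined_loss", "total_loss"]


@dataclass
class LossConfig:
    ce_weight: float = 0.3
    dice_weight: float = 0.7
    branch_weights: tuple = (0.7, 0.1, 0.1, 0.1)
    dice_eps: float = 1e-5

    def validate(self):
        if min(self.ce_weight, self.dice_weight, *self.branch_weights) < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if abs(sum(self.branch_weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"branch weights {self.branch_weights} must sum to 1")


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer [B,H,W] mask -> float [B,K,H,W] one-hot encoding."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ShapeError(
            f"mask labels in [{mask.min()}, {mask.max()}] out of range "
            f"for {num_classes} classes")
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[mask], -1, 1)


def dice_loss(pred_probs, target_onehot, eps: float = 1e-5) -> Tensor:
    """Soft Dice loss averaged over classes and batch."""
    p = as_tensor(pred_probs)
    y = np.asarray(target_onehot, dtype=np.float32)
    if p.shape != y.shape:
        raise ShapeError(
            f"prediction {p.shape} vs target {y.shape} shape mismatch")
    inter = (p * Tensor(y)).sum(axis=(2, 3))
    denom = p.sum(axis=(2, 3)) + Tensor(y.sum(axis=(2, 3)))
    dice = (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - dice.mean()


def cross_entropy(logits, target_mask) -> Tensor:
    """Multi-class CE on softmaxed logits, averaged over batch and pixels."""
    logits = as_tensor(logits)
    K = logits.shape[1]
    y = one_hot(target_mask, K)
    logp = logits.log_softmax(axis=1)
    return -(logp * Tensor(y)).sum(axis=1).mean()


def combined_loss(logits, target_mask, cfg: LossConfig | None = None) -> Tensor:
    """``ce_weight * CE + dice_weight * Dice`` for one logits branch."""
    cfg = cfg or LossConfig()
    cfg.validate()
    logits = as_tensor(logits)
    K = logits.shape[1]
    ce = cross_entropy(logits, target_mask)
    dice = dice_loss(logits.softmax(axis=1), one_hot(target_mask, K),
                     eps=cfg.dice_eps)
    return cfg.ce_weight * ce + cfg.dice_weight * dice


def total_loss(bundle: LogitsBundle, target_mask,
               cfg: LossConfig | None = None):
    """Deep-supervision objective; returns (scalar loss, branch breakdown).

    Auxiliary logits are upsampled to the full target resolution before
    scoring, so thin structures in the labels are never aliased away.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    target_mask = np.asarray(target_mask)
    H, W = target_mask.shape[-2:]
    branches = [bundle.main, bundle.aux8, bundle.aux16, bundle.aux32]
    names = ["main", "aux8", "aux16", "aux32"]
    total = None
    breakdown = {}
    for w, name, logits in zip(cfg.branch_weights, names, branches):
        if logits is None:
            raise ConfigurationError(f"missing {name} logits branch")
        logits = resize_bilinear(as_tensor(logits), H, W)
        branch = combined_loss(logits, target_mask, cfg)
        breakdown[name] = float(branch.data)
        term = w * branch
        total = term if total is None else total + term
    return total, breakdown
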