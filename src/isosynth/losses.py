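"""Training losses: L1 regression, soft Dice segmentation, and their sum.

The regression loss is the L1 norm of the intensity error.  The printed
objective is a sum of absolute differences; the optimized quantity here is
the per-voxel MEAN so that the relative weight of the segmentation term is
independent of patch size (both are reported).  The segmentation loss is one
minus the soft Dice overlap between the one-hot ground-truth labels and the
segmenter's probability maps, averaged over classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume

__all__ = [
    "LossConfig",
    "regression_loss",
    "regression_loss_grad",
    "one_hot",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "combined_loss",
]


@dataclass
class LossConfig:
    lam: float = 0.25          # relative weight of the segmentation loss
    dice_smooth: float = 1e-5  # epsilon in the soft Dice ratio

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")


def _as_array(x) -> np.ndarray:
    return np.asarray(x.data if hasattr(x, "data") and not isinstance(x, np.ndarray) else x,
                      dtype=np.float64)


def regression_loss(y, yhat, reduction: str = "mean") -> float:
    """L1 intensity error; ``reduction`` 'mean' (optimized) or 'sum' (as printed)."""
    y, yhat = _as_array(y), _as_array(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    err = np.abs(y - yhat)
    if reduction == "sum":
        return float(err.sum())
    if reduction == "mean":
        return float(err.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def regression_loss_grad(y, yhat) -> np.ndarray:
    """d(mean L1)/d(yhat): sign(yhat - y) / N."""
    y, yhat = _as_array(y), _as_array(yhat)
    return np.sign(yhat - y) / y.size


def one_hot(labels: LabelVolume | np.ndarray, codes: list[int]) -> np.ndarray:
    """(K, D, H, W) one-hot encoding over an explicit channel -> code order."""
    data = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    present = set(int(c) for c in np.unique(data))
    if not present <= set(codes):
        raise ValueError(f"labels contain codes {sorted(present - set(codes))} "
                         "absent from the channel list")
    return np.stack([(data == c) for c in codes]).astype(np.float64)


def soft_dice_loss(labels, probs: np.ndarray, codes: list[int] | None = None,
                   smooth: float = 1e-5) -> float:
    """1 - mean_k (2 sum G_k P_k + eps) / (sum G_k + sum P_k + eps)."""
    probs = np.asarray(probs, dtype=np.float64)
    if codes is None:
        codes = list(range(probs.shape[0]))
    if probs.shape[0] != len(codes):
        raise ValueError(f"{probs.shape[0]} channels but {len(codes)} codes")
    g = one_hot(labels, codes)
    if g.shape != probs.shape:
        raise ValueError(f"shape mismatch: one-hot {g.shape} vs probs {probs.shape}")
    inter = (g * probs).sum(axis=(1, 2, 3))
    sums = g.sum(axis=(1, 2, 3)) + probs.sum(axis=(1, 2, 3))
    dice = (2 * inter + smooth) / (sums + smooth)
    return float(1.0 - dice.mean())


def soft_dice_loss_grad(labels, probs: np.ndarray, codes: list[int] | None = None,
                        smooth: float = 1e-5) -> np.ndarray:
    """d(soft Dice loss)/d(probs), shape (K, D, H, W)."""
    probs = np.asarray(probs, dtype=np.float64)
    if codes is None:
        codes = list(range(probs.shape[0]))
    g = one_hot(labels, codes)
    k = probs.shape[0]
    inter = (g * probs).sum(axis=(1, 2, 3))
    denom = g.sum(axis=(1, 2, 3)) + probs.sum(axis=(1, 2, 3)) + smooth
    num = 2 * inter + smooth
    # d dice_k / d P_k(v) = (2 G_k(v) * denom - num) / denom^2
    ddice = (2 * g * denom[:, None, None, None] - num[:, None, None, None]) / \
        (denom ** 2)[:, None, None, None]
    return -ddice / k


def combined_loss(y, yhat, labels, probs, cfg: LossConfig,
                  codes: list[int] | None = None) -> dict[str, float]:
    """L = Lreg + lambda * Lseg; returns all three terms."""
    lreg = regression_loss(y, yhat, "mean")
    lseg = soft_dice_loss(labels, probs, codes, cfg.dice_smooth)
    return {
        "loss": lreg + cfg.lam * lseg,
        "loss_reg": lreg,
        "loss_seg": lseg,
        "loss_reg_sum": regression_loss(y, yhat, "sum"),
    }
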