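"""Soft-Dice training loss on the foreground probability channel."""

from __future__ import annotations

import numpy as np

__all__ = ["dice_loss", "dice_loss_grad"]

SMOOTH = 1e-5


def dice_loss(pred_fg: np.ndarray, target: np.ndarray, smooth: float = SMOOTH) -> float:
    """``1 - (2*sum(p*g) + s) / (sum(p) + sum(g) + s)``.

    Zero iff prediction matches a binary target exactly (up to the smoothing
    term ``s``, which also makes the empty-target / empty-prediction case
    well defined with loss -> 0).
    """
    p = np.asarray(pred_fg, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    return 1.0 - num / den


def dice_loss_grad(
    pred_fg: np.ndarray, target: np.ndarray, smooth: float = SMOOTH
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the foreground probabilities."""
    p = np.asarray(pred_fg, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    loss = 1.0 - num / den
    grad = -(2.0 * g * den - num) / den**2
    return loss, grad.astype(np.float32)
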