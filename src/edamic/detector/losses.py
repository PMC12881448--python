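"""Detection losses: binary cross-entropy and its soft focal generalization.

``soft_focal_loss`` modulates per-pixel BCE by ``|target - pred| ** gamma``,
which accepts continuous (soft) heatmap targets and reduces exactly to BCE
at ``gamma = 0``. Predictions are clamped to ``[eps, 1 - eps]`` inside the
logs so the loss is always finite.
"""

from __future__ import annotations

import numpy as np

from edamic.detector import autodiff as ad

EPS = 1e-7


def binary_cross_entropy(pred: np.ndarray, target: np.ndarray,
                         eps: float = EPS) -> float:
    pred = np.clip(np.asarray(pred, float), eps, 1.0 - eps)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes must match")
    per_px = -target * np.log(pred) - (1.0 - target) * np.log(1.0 - pred)
    return float(np.mean(per_px))


def soft_focal_loss(pred: np.ndarray, target: np.ndarray,
                    gamma: float = 2.0, eps: float = EPS) -> float:
    """Mean over pixels of ``|t - p|^gamma * BCE(p, t)``; BCE at gamma=0."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes must match")
    clamped = np.clip(pred, eps, 1.0 - eps)
    bce = -target * np.log(clamped) - (1.0 - target) * np.log(1.0 - clamped)
    mod = np.abs(target - pred) ** gamma
    return float(np.mean(mod * bce))


def soft_focal_loss_node(pred: "ad.Tensor", target: np.ndarray,
                         gamma: float = 2.0, eps: float = EPS) -> "ad.Tensor":
    """Autodiff version for training; same formula as soft_focal_loss."""
    t = ad.Tensor(np.asarray(target, float))
    clamped = ad.clamp(pred, eps, 1.0 - eps)
    one = ad.Tensor(1.0)
    bce = ad.sub(
        ad.mul(ad.Tensor(-t.data), ad.log(clamped)),
        ad.mul(ad.Tensor(1.0 - t.data), ad.log(ad.sub(one, clamped))),
    )
    if gamma == 0:
        return ad.mean(bce)
    mod = ad.pow_const(ad.abs_(ad.sub(t, pred)), gamma)
    return ad.mean(ad.mul(mod, bce))
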