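"""Segmentation loss functions: binary cross-entropy, Dice, weighted Hausdorff.

All three compare a probability map ``p`` (values in [0, 1]) with a binary
ground-truth mask ``g`` over the N pixels of the image:

* BCE (distribution-based):  −(1/N) Σ [g·log p + (1−g)·log(1−p)], with p
  clipped to [ε, 1−ε] so the loss stays finite at saturated predictions.
* Dice (region-based):  1 − (2 Σ p·g + s) / (Σ p + Σ g + s), a soft,
  differentiable complement of the Dice similarity coefficient.  The
  smoothing constant s makes the empty-vs-empty case well defined (loss 0).
* Weighted Hausdorff (boundary-based), after Ribera et al.'s differentiable
  surrogate: one term averages, over the predicted probability mass, the
  distance to the nearest ground-truth pixel; the symmetric term takes, for
  each ground-truth pixel, a generalized (power-α, α ≪ 0, i.e. a soft
  minimum) mean over pixels of p·d + (1−p)·d_max.  Distances are in pixel
  units; the loss is 0 when p is exactly the indicator of g.

``*_grad`` variants return (loss, dloss/dp) for gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LossConfig:
    """Numerical constants the printed loss formulas omit."""

    bce_clip_epsilon: float = 1e-7
    dice_smooth: float = 1e-6
    whd_alpha: float = -9.0
    whd_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.bce_clip_epsilon <= 0 or self.dice_smooth <= 0 or self.whd_epsilon <= 0:
            raise ValueError("epsilons must be > 0")


DEFAULT_LOSS_CONFIG = LossConfig()


def _check_shapes(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs ground truth {g.shape}")


def bce_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG) -> float:
    loss, _ = bce_loss_grad(p, g, cfg, need_grad=False)
    return loss


def bce_loss_grad(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG, need_grad: bool = True
):
    _check_shapes(p, g)
    eps = cfg.bce_clip_epsilon
    pc = np.clip(p, eps, 1.0 - eps)
    g = g.astype(pc.dtype)
    n = pc.size
    loss = float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).sum() / n)
    if not need_grad:
        return loss, None
    grad = (-g / pc + (1.0 - g) / (1.0 - pc)) / n
    # clipped pixels are flat
    grad = np.where((p > eps) & (p < 1.0 - eps), grad, 0.0)
    return loss, grad


def dice_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG) -> float:
    loss, _ = dice_loss_grad(p, g, cfg, need_grad=False)
    return loss


def dice_loss_grad(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG, need_grad: bool = True
):
    _check_shapes(p, g)
    g = g.astype(np.float64)
    p = p.astype(np.float64)
    s = cfg.dice_smooth
    num = 2.0 * (p * g).sum() + s
    den = p.sum() + g.sum() + s
    loss = float(1.0 - num / den)
    if not need_grad:
        return loss, None
    grad = (num / den**2) - 2.0 * g / den
    return loss, grad


def weighted_hausdorff_loss(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG
) -> float:
    loss, _ = weighted_hausdorff_loss_grad(p, g, cfg, need_grad=False)
    return loss


def weighted_hausdorff_loss_grad(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = DEFAULT_LOSS_CONFIG, need_grad: bool = True
):
    """Weighted Hausdorff surrogate and its gradient with respect to p.

    term 1:  (1 / (Σp + ε)) Σ_x p_x · d(x, Y)            (Y = GT foreground)
    term 2:  (1/|Y|) Σ_y  M_α over all pixels x of  [p_x d(x,y) + (1−p_x) d_max]
    with M_α(f) = (mean (f+ε)^α)^(1/α), α < 0 acting as a soft minimum and
    d_max the image diagonal.  Raises on an empty ground truth, where the
    distance to the foreground set is undefined.
    """
    _check_shapes(p, g)
    g = np.asarray(g)
    if g.sum() == 0:
        raise ValueError("weighted Hausdorff loss is undefined for an empty ground truth")
    p = p.astype(np.float64)
    alpha = cfg.whd_alpha
    eps = cfg.whd_epsilon
    h, w = p.shape

    # distance from every pixel to the nearest GT pixel
    d_to_gt = ndimage.distance_transform_edt(g == 0)
    s = p.sum()
    term1 = (p * d_to_gt).sum() / (s + eps)

    # pairwise distances between all pixels and GT pixels
    yy, xx = np.nonzero(g)
    gt_pts = np.stack([yy, xx], axis=1).astype(np.float64)  # (m, 2)
    ry, rx = np.indices(p.shape)
    pix = np.stack([ry.ravel(), rx.ravel()], axis=1).astype(np.float64)  # (n, 2)
    d_max = float(np.hypot(h - 1, w - 1))
    pf = p.ravel()

    m = gt_pts.shape[0]
    n = pix.shape[0]
    term2 = 0.0
    grad2 = np.zeros(n) if need_grad else None
    # chunk over GT points to bound the (n × m) distance matrix
    chunk = max(1, int(2e7) // n)
    for lo in range(0, m, chunk):
        pts = gt_pts[lo : lo + chunk]
        diff = pix[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))  # (n, k)
        f = pf[:, None] * d + (1.0 - pf[:, None]) * d_max + eps
        fa = f**alpha
        mean_fa = fa.mean(axis=0)  # (k,)
        m_alpha = mean_fa ** (1.0 / alpha)
        term2 += m_alpha.sum()
        if need_grad:
            # d m_alpha / d p_x = m_alpha^(1-α)/n · f^(α−1) · (d − d_max)
            coeff = (m_alpha ** (1.0 - alpha))[None, :] / n
            grad2 += (coeff * fa / f * (d - d_max)).sum(axis=1)
    term2 /= m

    loss = float(term1 + term2)
    if not need_grad:
        return loss, None
    grad1 = d_to_gt.ravel() / (s + eps) - (p * d_to_gt).sum() / (s + eps) ** 2
    grad = (grad1 + grad2 / m).reshape(p.shape)
    return loss, grad


_LOSSES = {
    "bce": bce_loss_grad,
    "dice": dice_loss_grad,
    "whd": weighted_hausdorff_loss_grad,
}


def get_loss(name: str):
    """Look up a loss by name ("bce" | "dice" | "whd"); returns (loss, grad) fn."""
    try:
        return _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(_LOSSES)}") from None
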