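"""Training objectives.

Image reconstruction is scored with the structural similarity index
(SSIM) over local windows; the loss is ``1 - SSIM`` since SSIM is a
similarity.  Segmentation combines binary cross-entropy, a soft Dice
term and a pixel-wise false-positive penalty; the cross-entropy is
written with the conventional negative sign so that the total is
minimized at a perfect prediction.  Gradient companions of both losses
are provided for the NumPy training loop and are verified against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "LossConfig",
    "ssim",
    "image_loss",
    "seg_loss",
    "total_loss",
    "ssim_and_grad",
    "seg_loss_and_grad",
]

_DICE_SMOOTH = 1e-6


@dataclass(frozen=True)
class LossConfig:
    """Loss hyper-parameters.

    ``ssim_k1``/``ssim_k2`` are the stabilizing constants of the SSIM
    numerator/denominator at unit dynamic range, the standard
    ``(0.01)^2`` and ``(0.03)^2``.  ``eps`` clamps predicted
    probabilities away from {0, 1} before logarithms.
    """

    ssim_window: int = 11
    ssim_k1: float = 0.01 ** 2
    ssim_k2: float = 0.03 ** 2
    w_image: float = 1.0
    w_seg: float = 1.0
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0:
            raise ValueError("ssim constants must be positive")
        if self.w_image < 0 or self.w_seg < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 < self.eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# SSIM with a uniform local window.  Statistics use 'valid' windows only
# (a half-window border is cropped) so that the adjoint of the box filter
# is again a box filter and the analytic gradient is exact.
# ---------------------------------------------------------------------------

def _box_valid(img: np.ndarray, w: int) -> np.ndarray:
    h = w // 2
    return uniform_filter(img, size=w, mode="constant")[h:-h, h:-h]


def _box_adjoint(g: np.ndarray, w: int, shape: tuple) -> np.ndarray:
    h = w // 2
    full = np.zeros(shape, dtype=np.float32)
    full[h:-h, h:-h] = g
    return uniform_filter(full, size=w, mode="constant")


def _ssim_stats(x: np.ndarray, y: np.ndarray, cfg: LossConfig):
    w = cfg.ssim_window
    mx, my = _box_valid(x, w), _box_valid(y, w)
    vx = _box_valid(x * x, w) - mx * mx
    vy = _box_valid(y * y, w) - my * my
    cxy = _box_valid(x * y, w) - mx * my
    c1 = np.float32(cfg.ssim_k1)
    c2 = np.float32(cfg.ssim_k2)
    a1 = 2.0 * mx * my + c1
    a2 = 2.0 * cxy + c2
    b1 = mx * mx + my * my + c1
    b2 = vx + vy + c2
    return mx, my, a1, a2, b1, b2


def ssim(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Mean local SSIM between two images in [0, 1]; symmetric, in [-1, 1]."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    if min(x.shape) < cfg.ssim_window:
        raise ValueError("images smaller than the SSIM window")
    _, _, a1, a2, b1, b2 = _ssim_stats(x, y, cfg)
    return float(((a1 * a2) / (b1 * b2)).mean())


def ssim_and_grad(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()):
    """SSIM value and the gradient of mean SSIM with respect to ``x``."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    w = cfg.ssim_window
    mx, my, a1, a2, b1, b2 = _ssim_stats(x, y, cfg)
    s_map = (a1 * a2) / (b1 * b2)
    g = np.float32(1.0 / s_map.size)
    # partials of mean(S) with respect to the window statistics
    g_mx = g * (2.0 * my * a2 * b1 * b2 - a1 * a2 * 2.0 * mx * b2) / (b1 * b2) ** 2
    g_cxy = g * 2.0 * a1 / (b1 * b2)
    g_vx = g * (-a1 * a2) / (b1 * b2 ** 2)
    # chain through mu_x = B(x), v_x = B(x^2) - mu_x^2, c_xy = B(xy) - mu_x mu_y
    g_mu_total = g_mx - 2.0 * mx * g_vx - my * g_cxy
    dx = (
        _box_adjoint(g_mu_total, w, x.shape)
        + 2.0 * x * _box_adjoint(g_vx, w, x.shape)
        + y * _box_adjoint(g_cxy, w, x.shape)
    )
    return float(s_map.mean()), dx.astype(np.float32)


def image_loss(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """``1 - SSIM``; zero exactly when the images agree everywhere."""
    return 1.0 - ssim(x, y, cfg)


def seg_loss(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Segmentation loss: BCE + (1 - soft Dice) + false-positive rate."""
    return seg_loss_and_grad(x, y, cfg)[0]


def seg_loss_and_grad(x: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()):
    """Loss and gradient with respect to the predicted probabilities.

    ``x`` holds probabilities in [0, 1] (clamped to [eps, 1-eps] before
    logs); ``y`` is the binary ground-truth mask.  The Dice term uses the
    soft intersection ``sum(x * y)`` so gradients flow through ``x``, and
    a small additive smoothing guards empty masks.
    """
    # computed in the caller's precision: the training loop passes float32,
    # while float64 inputs keep finite-difference verification meaningful
    dt = np.result_type(np.asarray(x).dtype, np.float32)
    x = np.asarray(x, dtype=dt)
    y = np.asarray(y, dtype=dt)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    eps = dt.type(cfg.eps)
    xc = np.clip(x, eps, 1.0 - eps)
    n = dt.type(x.size)
    bce = float(-(y * np.log(xc) + (1.0 - y) * np.log(1.0 - xc)).mean())
    sx = float(xc.sum())
    sy = float(y.sum())
    sxy = float((xc * y).sum())
    denom = sx + sy + _DICE_SMOOTH
    dice_term = 1.0 - (2.0 * sxy + _DICE_SMOOTH) / denom
    fp = float((xc * (1.0 - y)).mean())
    loss = bce + dice_term + fp
    grad = -(y / xc - (1.0 - y) / (1.0 - xc)) / n
    grad += -(2.0 * y * denom - (2.0 * sxy + _DICE_SMOOTH)) / denom ** 2
    grad += (1.0 - y) / n
    return float(loss), grad.astype(dt, copy=False)


def total_loss(l_image: float, l_seg: float, cfg: LossConfig = LossConfig()) -> float:
    """Weighted combination ``w_image * L_image + w_seg * L_seg``."""
    return cfg.w_image * l_image + cfg.w_seg * l_seg
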