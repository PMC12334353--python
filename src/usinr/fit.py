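"""Training loop: Adam + cosine annealing + gradient EMA amplification.

One model is fitted per acquired volume.  Batches are whole frames
(the SSIM objective needs intact spatial windows), sampled in a
shuffled order each epoch; one epoch is one pass over every frame.
Gradients pass through a low-pass EMA amplification filter (the
"grokfast" trick) before Adam, which accelerates convergence of the
slow gradient components and lets a volume be fitted in a few hundred
epochs.  Everything is driven by a single master seed, so a run is
bit-reproducible on a fixed BLAS configuration.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScanGeometry, frame_grid_world, normalize_coords
from .losses import LossConfig, seg_loss_and_grad, ssim_and_grad, total_loss
from .network import InrConfig, InrModel, init_model, positional_encode
from .phantom import FrameSet

__all__ = ["TrainConfig", "cosine_lr", "grokfast_filter", "fit_inr"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule and seeding.

    Defaults follow the reference protocol: Adam for 500 epochs, learning
    rate 1e-3 cosine-annealed to 1e-6, EMA filter alpha=0.98 with
    amplification lambda=2.
    """

    epochs: int = 500
    lr_init: float = 1e-3
    lr_min: float = 1e-6
    grokfast_alpha: float = 0.98
    grokfast_lambda: float = 2.0
    frames_per_step: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if not 0.0 < self.grokfast_alpha < 1.0:
            raise ValueError("grokfast_alpha must lie in (0, 1)")
        if self.grokfast_lambda < 0.0:
            raise ValueError("grokfast_lambda must be non-negative")
        if self.frames_per_step < 1:
            raise ValueError("frames_per_step must be positive")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate, stepped per epoch.

    ``lr(e) = lr_min + (lr_init - lr_min) (1 + cos(pi e / epochs)) / 2``;
    monotone non-increasing from lr_init at epoch 0 to lr_min at the
    final epoch count.
    """
    e = min(max(epoch, 0), cfg.epochs)
    return cfg.lr_min + 0.5 * (cfg.lr_init - cfg.lr_min) * (
        1.0 + np.cos(np.pi * e / cfg.epochs)
    )


def grokfast_filter(grad: np.ndarray, ema_state: np.ndarray | None,
                    cfg: TrainConfig) -> tuple:
    """EMA gradient amplification: returns (filtered_grad, new_ema).

    ``ema <- alpha * ema + (1 - alpha) * grad`` and the filtered gradient
    is ``grad + lambda * ema``.  With lambda = 0 the filter is the
    identity on gradients; for a constant gradient stream the filtered
    gradient approaches ``(1 + lambda) * grad``.
    """
    if ema_state is None:
        ema_state = np.zeros_like(grad)
    new_ema = cfg.grokfast_alpha * ema_state + (1.0 - cfg.grokfast_alpha) * grad
    return grad + cfg.grokfast_lambda * new_ema, new_ema


class _Adam:
    """Per-parameter Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2, self.eps = np.float32(b1), np.float32(b2), np.float32(eps)
        self.t = 0

    def step(self, params: list, grads: list, lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        lr32 = np.float32(lr)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= lr32 * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _precompute_features(frames: FrameSet, geom: ScanGeometry,
                         inr_cfg: InrConfig) -> list:
    """Positional-encoded pixel coordinates per frame (fixed across epochs)."""
    feats = []
    for ang in frames.angles_deg:
        pts = frame_grid_world(geom, float(ang))
        feats.append(
            positional_encode(normalize_coords(pts, geom), inr_cfg.pe_bands)
        )
    return feats


def fit_inr(
    frames: FrameSet,
    geom: ScanGeometry | None = None,
    inr_cfg: InrConfig = InrConfig(),
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    log_every: int = 1,
) -> tuple:
    """Fit one coordinate network to one frame set.

    Returns ``(model, log)`` where ``log`` is a DataFrame with one row
    per logged epoch: epoch, lr, L_image, L_seg, total (epoch means).
    Raises if the loss turns non-finite, naming the epoch.
    """
    geom = geom or frames.geom
    shape = (geom.rows, geom.cols)
    npx = shape[0] * shape[1]
    feats = _precompute_features(frames, geom, inr_cfg)
    model = init_model(
        inr_cfg, seed=train_cfg.seed,
        coord_scale=(geom.axial_extent_mm, geom.lateral_extent_mm),
    )
    core = model.core
    params = core.parameters()
    adam = _Adam(params)
    ema: list = [None] * len(params)
    rng = np.random.default_rng(train_cfg.seed + 1)
    masks32 = frames.mask.astype(np.float32)
    use_seg = loss_cfg.w_seg > 0
    use_img = loss_cfg.w_image > 0
    records = []
    t0 = time.perf_counter()
    for epoch in range(train_cfg.epochs):
        lr = cosine_lr(epoch, train_cfg)
        order = rng.permutation(frames.n_frames)
        ep_img, ep_seg, n_steps = 0.0, 0.0, 0
        for start in range(0, frames.n_frames, train_cfg.frames_per_step):
            idx = order[start:start + train_cfg.frames_per_step]
            batch = np.concatenate([feats[i] for i in idx], axis=0)
            out = core.forward(batch, want_cache=True)
            dout = np.zeros_like(out)
            l_img_sum, l_seg_sum = 0.0, 0.0
            for k, fi in enumerate(idx):
                sl = slice(k * npx, (k + 1) * npx)
                if use_img:
                    pred_img = out[sl, 0].reshape(shape)
                    s_val, ds = ssim_and_grad(pred_img, frames.intensity[fi], loss_cfg)
                    l_img_sum += 1.0 - s_val
                    dout[sl, 0] = (-loss_cfg.w_image / len(idx)) * ds.ravel()
                if use_seg:
                    logits = out[sl, 1]
                    prob = 1.0 / (1.0 + np.exp(-logits))
                    l_seg, dseg = seg_loss_and_grad(
                        prob.reshape(shape), masks32[fi], loss_cfg
                    )
                    l_seg_sum += l_seg
                    dout[sl, 1] = (loss_cfg.w_seg / len(idx)) * (
                        dseg.ravel() * prob * (1.0 - prob)
                    )
            grads = core.backward(dout)
            filtered = []
            for j, g in enumerate(grads):
                fg, ema[j] = grokfast_filter(g, ema[j], train_cfg)
                filtered.append(fg)
            adam.step(params, filtered, lr)
            ep_img += l_img_sum / len(idx)
            ep_seg += l_seg_sum / len(idx)
            n_steps += 1
        mean_img = ep_img / n_steps
        mean_seg = ep_seg / n_steps
        tot = total_loss(mean_img, mean_seg, loss_cfg)
        if not np.isfinite(tot):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        if epoch % log_every == 0 or epoch == train_cfg.epochs - 1:
            records.append(
                {"epoch": epoch, "lr": lr, "L_image": mean_img,
                 "L_seg": mean_seg, "total": tot,
                 "wall_s": time.perf_counter() - t0}
            )
    log = pd.DataFrame.from_records(records)
    return model, log
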