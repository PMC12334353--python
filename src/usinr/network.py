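"""Coordinate network: F(x, y, z) -> (intensity, mask probability).

A sinusoidal multilayer perceptron (SIREN) with additive skip
connections consumes a positional encoding of the normalized 3D
coordinate and emits two channels: B-mode intensity (linear head,
clamped to [0, 1] only at rendering time) and a segmentation logit
(sigmoid applied on evaluation).  One network represents exactly one
acquired volume; evaluation cost per point is constant regardless of
how many frames were used for training.

The implementation is plain NumPy with hand-written reverse-mode
gradients: the architecture is small and fixed, and single-threaded
BLAS keeps both training and inference fast enough on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "InrConfig",
    "InrModel",
    "positional_encode",
    "init_model",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

_HALF_PI = np.float32(np.pi / 2.0)


def _fast_sin(z: np.ndarray) -> np.ndarray:
    # cos has the faster SIMD kernel in this numpy build; sin(z) = cos(z - pi/2)
    return np.cos(z - _HALF_PI)


@dataclass(frozen=True)
class InrConfig:
    """Architecture of the coordinate network.

    ``pe_bands`` counts sine/cosine frequency pairs per coordinate, so
    the input dimension is ``3 * (1 + 2 * pe_bands)`` — 93 at the
    default 15 bands.  ``n_layers`` counts linear layers including the
    2-channel output head; additive skip connections join same-width
    activations every ``skip_every`` hidden layers.
    """

    pe_bands: int = 15
    n_layers: int = 10
    width: int = 256
    skip_every: int = 2
    siren_omega: float = 30.0
    out_dim: int = 2

    def __post_init__(self) -> None:
        if self.pe_bands < 0:
            raise ValueError("pe_bands must be non-negative")
        if self.n_layers < 2:
            raise ValueError("n_layers must be at least 2")
        if self.width < 1:
            raise ValueError("width must be positive")
        if self.skip_every < 1:
            raise ValueError("skip_every must be positive")
        if self.out_dim != 2:
            raise ValueError("the network emits exactly (intensity, mask logit)")

    @property
    def input_dim(self) -> int:
        return 3 * (1 + 2 * self.pe_bands)

    def layer_dims(self) -> list:
        return [self.input_dim] + [self.width] * (self.n_layers - 1) + [self.out_dim]


def positional_encode(coords: np.ndarray, pe_bands: int) -> np.ndarray:
    """Harmonic encoding of normalized coordinates.

    For each coordinate value ``x`` emits ``(x, sin(2^0 x), cos(2^0 x),
    ..., sin(2^(B-1) x), cos(2^(B-1) x))`` and concatenates the three
    per-axis blocks.  ``pe_bands = 0`` is the identity.
    """
    c = np.asarray(coords, dtype=np.float32)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords must have shape (N, 3)")
    if pe_bands == 0:
        return c.copy()
    n = c.shape[0]
    out = np.empty((n, 3 * (1 + 2 * pe_bands)), dtype=np.float32)
    block = 1 + 2 * pe_bands
    for axis in range(3):
        x = c[:, axis]
        out[:, axis * block] = x
        for j in range(pe_bands):
            k = np.float32(2.0 ** j)
            out[:, axis * block + 1 + 2 * j] = _fast_sin(k * x)
            out[:, axis * block + 2 + 2 * j] = np.cos(k * x)
    return out


class _SirenCore:
    """Weights plus forward/backward passes (float32 throughout)."""

    def __init__(self, config: InrConfig, seed: int):
        rng = np.random.default_rng(seed)
        dims = config.layer_dims()
        omega = config.siren_omega
        self.W: list = []
        self.b: list = []
        for i in range(config.n_layers):
            fan_in = dims[i]
            if i == 0:
                bound = 1.0 / fan_in
            else:
                bound = np.sqrt(6.0 / fan_in) / omega
            self.W.append(
                rng.uniform(-bound, bound, size=(fan_in, dims[i + 1])).astype(np.float32)
            )
            self.b.append(np.zeros(dims[i + 1], dtype=np.float32))
        self.omega = np.float32(omega)
        self.skip_every = config.skip_every
        self._cache = None

    # -- parameter bookkeeping ---------------------------------------------
    def parameters(self) -> list:
        return self.W + self.b

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def _skip_source(self, i: int, acts: list, shape: tuple) -> int | None:
        """Index into ``acts`` feeding an additive skip at hidden layer i."""
        if i >= self.skip_every and i % self.skip_every == 0:
            src = i - self.skip_every + 1
            if acts[src].shape == shape:
                return src
        return None

    def forward(self, X: np.ndarray, want_cache: bool = False) -> np.ndarray:
        n = len(self.W)
        acts = [X]
        coss = []
        a = X
        for i in range(n - 1):
            z = a @ self.W[i]
            z += self.b[i]
            z *= self.omega  # sine layers compute sin(omega * (Wx + b))
            if want_cache:
                coss.append(np.cos(z))
            # sin in place via the faster cos kernel
            z -= _HALF_PI
            np.cos(z, out=z)
            a = z
            src = self._skip_source(i, acts, a.shape)
            if src is not None:
                a = a + acts[src]
            acts.append(a)
        out = a @ self.W[-1]
        out += self.b[-1]
        if want_cache:
            self._cache = (acts, coss)
        return out

    def backward(self, dout: np.ndarray) -> list:
        """Parameter gradients for the batch whose forward was cached."""
        if self._cache is None:
            raise RuntimeError("forward(..., want_cache=True) must run first")
        acts, coss = self._cache
        n = len(self.W)
        dW: list = [None] * n
        db: list = [None] * n
        # column sums via BLAS matvec (much faster than ufunc reduction)
        ones = np.ones(dout.shape[0], dtype=np.float32)
        dW[-1] = acts[-1].T @ dout
        db[-1] = ones @ dout
        da = dout @ self.W[-1].T
        pending: dict = {}
        for i in range(n - 2, -1, -1):
            if (i + 1) in pending:
                da += pending.pop(i + 1)
            src = self._skip_source(i, acts, da.shape)
            if src is not None:
                # the skip branch receives da unchanged; keep a copy since
                # da is consumed in place below
                pending[src] = da.copy()
            dz = da
            dz *= coss[i]
            dz *= self.omega
            dW[i] = acts[i].T @ dz
            db[i] = ones @ dz
            if i > 0:
                da = dz @ self.W[i].T
        self._cache = None
        return dW + db


@dataclass
class InrModel:
    """A trained (or fresh) coordinate network bound to one volume.

    ``coord_scale`` records the world-to-cube normalization
    (axial_extent_mm, lateral_extent_mm) so that the model can be
    evaluated directly at world coordinates in mm.
    """

    config: InrConfig
    core: _SirenCore
    coord_scale: tuple = (1.0, 1.0)

    def n_parameters(self) -> int:
        return self.core.n_parameters()

    def normalize(self, coords_mm: np.ndarray) -> np.ndarray:
        c = np.asarray(coords_mm, dtype=np.float32)
        out = np.empty_like(c)
        ax, lat = self.coord_scale
        out[..., 0] = 2.0 * c[..., 0] / ax - 1.0
        out[..., 1] = c[..., 1] / (lat / 2.0)
        out[..., 2] = c[..., 2] / (lat / 2.0)
        return out


def init_model(config: InrConfig, seed: int, coord_scale: tuple = (1.0, 1.0)) -> InrModel:
    """Fresh model with the SIREN initialization.

    First layer uniform in +/- 1/fan_in, deeper layers uniform in
    +/- sqrt(6/fan_in)/omega; every sine layer scales its pre-activation
    by omega, which keeps hidden pre-activations at unit scale under
    this init.  Deterministic for a given seed.
    """
    return InrModel(config=config, core=_SirenCore(config, seed),
                    coord_scale=tuple(float(v) for v in coord_scale))


def evaluate(model: InrModel, coords_mm: np.ndarray, tile: int = 1 << 18) -> tuple:
    """Sample the network at world coordinates (mm).

    Returns ``(intensity, mask_probability)`` with the mask head passed
    through a sigmoid.  Intensity is the raw linear output; clamp to
    [0, 1] when rendering.  Evaluation is pure and tiled to bound
    memory, and never touches any training data.
    """
    c = np.asarray(coords_mm, dtype=np.float32)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords must have shape (N, 3)")
    if not np.isfinite(c).all():
        raise ValueError("coordinates must be finite")
    n = c.shape[0]
    inten = np.empty(n, dtype=np.float32)
    prob = np.empty(n, dtype=np.float32)
    norm = model.normalize(c)
    for s in range(0, n, tile):
        sl = slice(s, min(s + tile, n))
        feats = positional_encode(norm[sl], model.config.pe_bands)
        out = model.core.forward(feats)
        inten[sl] = out[:, 0]
        prob[sl] = 1.0 / (1.0 + np.exp(-out[:, 1]))
    return inten, prob


def save_checkpoint(model: InrModel, path: str | Path) -> dict:
    """Write weights (.npz) plus a JSON config sidecar; returns metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"W{i}": w for i, w in enumerate(model.core.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.core.b)})
    np.savez(path, **arrays)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = npz_path.with_suffix(".json")
    meta = {
        "config": asdict(model.config),
        "coord_scale": list(model.coord_scale),
        "n_parameters": model.n_parameters(),
        "weight_bytes": npz_path.stat().st_size,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return meta


def load_checkpoint(path: str | Path) -> InrModel:
    """Restore a checkpoint; weight shapes are validated against the config."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    meta = json.loads(npz_path.with_suffix(".json").read_text())
    config = InrConfig(**meta["config"])
    model = init_model(config, seed=0, coord_scale=tuple(meta["coord_scale"]))
    data = np.load(npz_path)
    for i in range(config.n_layers):
        w, b = data[f"W{i}"], data[f"b{i}"]
        if w.shape != model.core.W[i].shape or b.shape != model.core.b[i].shape:
            raise ValueError(
                f"checkpoint layer {i} has shape {w.shape}, config expects "
                f"{model.core.W[i].shape}"
            )
        model.core.W[i] = w.astype(np.float32)
        model.core.b[i] = b.astype(np.float32)
    return model
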