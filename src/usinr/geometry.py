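"""Rotational-sweep acquisition geometry.

A 1D-array transducer mounted on a motorized rotary acquires 2D B-mode
frames while rotating about the axial (depth) axis.  Every frame is a
planar raster whose pixels can be placed exactly in 3D once the rotation
angle is known: the rotation axis is the depth line through ``axis_col``,
at 0 degrees the image plane coincides with the x-y plane, and a pixel
with lateral offset ``l`` at angle theta maps to ``(x, l cos(theta),
l sin(theta))``.  All public interfaces use millimetres and degrees;
radians appear only inside trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScanGeometry",
    "GridSpec",
    "plan_sweep",
    "frame_to_world",
    "frame_grid_world",
    "normalize_coords",
    "denormalize_coords",
]

_DIV_TOL = 1e-9


@dataclass(frozen=True)
class ScanGeometry:
    """Sweep plan plus the per-frame image raster.

    Parameters
    ----------
    sweep_deg : float
        Total angular range of the sweep in degrees (typically 180).
    step_deg : float
        Angular increment between consecutive frames, degrees.
    axial_extent_mm : float
        Depth of the field of view (x direction, 0 at the transducer face).
    lateral_extent_mm : float
        Width of the field of view across the array.
    rows, cols : int
        Frame raster size; rows index depth, cols index the lateral axis.
    axis_col : float, optional
        Fractional column index of the rotation axis.  Defaults to the
        raster centre ``(cols - 1) / 2`` so that the two outermost pixel
        centres sit symmetrically at +/- lateral_extent/2.
    """

    sweep_deg: float
    step_deg: float
    axial_extent_mm: float
    lateral_extent_mm: float
    rows: int
    cols: int
    axis_col: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sweep_deg <= 0 or self.step_deg <= 0:
            raise ValueError("sweep_deg and step_deg must be positive")
        ratio = self.sweep_deg / self.step_deg
        if abs(ratio - round(ratio)) > _DIV_TOL * max(1.0, ratio):
            raise ValueError(
                f"step_deg={self.step_deg} does not divide sweep_deg="
                f"{self.sweep_deg}: sweep/step = {ratio}"
            )
        if self.axial_extent_mm <= 0 or self.lateral_extent_mm <= 0:
            raise ValueError("field-of-view extents must be positive")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("rows and cols must be at least 2")
        if self.axis_col is None:
            object.__setattr__(self, "axis_col", (self.cols - 1) / 2.0)

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.sweep_deg / self.step_deg))

    @property
    def angles_deg(self) -> np.ndarray:
        return plan_sweep(self.sweep_deg, self.step_deg)

    @property
    def axial_spacing_mm(self) -> float:
        """Pixel pitch along depth; pixel centres span the full extent."""
        return self.axial_extent_mm / (self.rows - 1)

    @property
    def lateral_spacing_mm(self) -> float:
        return self.lateral_extent_mm / (self.cols - 1)

    def to_dict(self) -> dict:
        return {
            "sweep_deg": self.sweep_deg,
            "step_deg": self.step_deg,
            "axial_extent_mm": self.axial_extent_mm,
            "lateral_extent_mm": self.lateral_extent_mm,
            "rows": self.rows,
            "cols": self.cols,
            "axis_col": self.axis_col,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{k: d[k] for k in (
            "sweep_deg", "step_deg", "axial_extent_mm", "lateral_extent_mm",
            "rows", "cols", "axis_col")})


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid in world coordinates (mm).

    Voxel centres sit at ``origin_mm + index * spacing_mm``.
    """

    origin_mm: tuple
    spacing_mm: tuple
    shape: tuple

    def __post_init__(self) -> None:
        if len(self.origin_mm) != 3 or len(self.spacing_mm) != 3 or len(self.shape) != 3:
            raise ValueError("origin_mm, spacing_mm and shape must have length 3")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive componentwise")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be at least 1 along every axis")
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "spacing_mm", tuple(float(v) for v in self.spacing_mm))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axes_mm(self) -> tuple:
        return tuple(
            self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an (N, 3) float32 array in raster order."""
        ax = self.axes_mm()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1).reshape(-1, 3).astype(np.float32)

    @classmethod
    def for_cylinder(cls, axial_extent_mm: float, lateral_extent_mm: float,
                     n: int) -> "GridSpec":
        """Isotropic-count grid covering the cylinder swept by the frames."""
        half = lateral_extent_mm / 2.0
        return cls(
            origin_mm=(0.0, -half, -half),
            spacing_mm=(axial_extent_mm / (n - 1), lateral_extent_mm / (n - 1),
                        lateral_extent_mm / (n - 1)),
            shape=(n, n, n),
        )


def plan_sweep(sweep_deg: float, step_deg: float) -> np.ndarray:
    """Frame angles of a rotational sweep, in degrees.

    The sweep is half-open: the final angle ``sweep_deg`` is excluded
    because for a 180-degree sweep that plane duplicates the 0-degree
    plane.  Hence 180/1.25 yields 144 angles, the count the acquisition
    protocol aims for.
    """
    if sweep_deg <= 0 or step_deg <= 0:
        raise ValueError("sweep_deg and step_deg must be positive")
    ratio = sweep_deg / step_deg
    n = round(ratio)
    if abs(ratio - n) > _DIV_TOL * max(1.0, ratio):
        raise ValueError(
            f"step_deg={step_deg} does not divide sweep_deg={sweep_deg}"
        )
    return np.arange(n, dtype=np.float64) * step_deg


def frame_to_world(
    geom: ScanGeometry,
    angle_deg: float,
    pixel_rows: Sequence[float] | np.ndarray,
    pixel_cols: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Map frame pixel indices at a given rotation angle to world mm.

    Returns an (N, 3) array of (x, y, z).  ``x`` is depth; the lateral
    offset ``l = (col - axis_col) * lateral_spacing`` rotates into the
    (y, z) plane.  The radial distance ``sqrt(y^2 + z^2) = |l|`` of a
    pixel is independent of the angle.
    """
    r = np.asarray(pixel_rows, dtype=np.float64)
    c = np.asarray(pixel_cols, dtype=np.float64)
    if r.shape != c.shape:
        raise ValueError("pixel_rows and pixel_cols must have the same shape")
    if np.any(r < 0) or np.any(r > geom.rows - 1) or np.any(c < 0) or np.any(c > geom.cols - 1):
        raise ValueError(
            f"pixel indices outside the {geom.rows}x{geom.cols} raster"
        )
    x = r * geom.axial_spacing_mm
    l = (c - geom.axis_col) * geom.lateral_spacing_mm
    th = np.deg2rad(angle_deg)
    return np.stack([x, l * np.cos(th), l * np.sin(th)], axis=-1)


def frame_grid_world(geom: ScanGeometry, angle_deg: float) -> np.ndarray:
    """World coordinates of every pixel of one frame, raster order (rows*cols, 3)."""
    rr, cc = np.meshgrid(
        np.arange(geom.rows), np.arange(geom.cols), indexing="ij"
    )
    return frame_to_world(geom, angle_deg, rr.ravel(), cc.ravel())


def normalize_coords(coords_mm: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Affine map from world mm into the network's [-1, 1]^3 cube.

    Depth ``x`` maps [0, axial_extent] onto [-1, 1]; the transverse axes
    are divided by lateral_extent/2.  Values outside the cube are allowed
    (extrapolation) and map affinely.
    """
    c = np.asarray(coords_mm, dtype=np.float32)
    out = np.empty_like(c)
    out[..., 0] = 2.0 * c[..., 0] / geom.axial_extent_mm - 1.0
    half = geom.lateral_extent_mm / 2.0
    out[..., 1] = c[..., 1] / half
    out[..., 2] = c[..., 2] / half
    return out


def denormalize_coords(coords_norm: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """Inverse of :func:`normalize_coords` (exact affine inverse)."""
    c = np.asarray(coords_norm, dtype=np.float64)
    out = np.empty_like(c)
    out[..., 0] = (c[..., 0] + 1.0) * geom.axial_extent_mm / 2.0
    half = geom.lateral_extent_mm / 2.0
    out[..., 1] = c[..., 1] * half
    out[..., 2] = c[..., 2] * half
    return out
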