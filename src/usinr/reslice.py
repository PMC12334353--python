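"""Arbitrary-coordinate sampling of a trained model, and the
nearest-neighbour scattered-data baseline it is compared against.

The network can be evaluated on any voxel grid or plane, including
resolutions and orientations never present in the acquisition; the
baseline answers the same queries by looking up the Euclidean-nearest
acquired pixel through a k-d tree.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import GridSpec, ScanGeometry, frame_grid_world
from .network import InrModel, evaluate
from .phantom import FrameSet
from .volumetry import dice, iou

__all__ = [
    "GridSpec",
    "VoxelVolume",
    "sample_volume",
    "reslice",
    "reslice_oblique",
    "oblique_plane_grid",
    "plane_grid",
    "frameset_point_cloud",
    "nn_interpolate",
    "NearestNeighborField",
    "compare_methods",
]


@dataclass
class VoxelVolume:
    """A sampled 3D grid: intensity in [0, 1] plus a binary mask."""

    grid: GridSpec
    intensity: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.intensity.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("array shapes must equal grid.shape")
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def sample_volume(model: InrModel, grid: GridSpec, threshold: float = 0.5,
                  tile: int = 1 << 18) -> VoxelVolume:
    """Evaluate the model at every voxel centre of ``grid``.

    Intensity is clamped to [0, 1]; the mask is ``probability >=
    threshold``.  Evaluation is tiled to bound memory and tiling does
    not change the result.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pts = grid.voxel_centers()
    inten, prob = evaluate(model, pts, tile=tile)
    return VoxelVolume(
        grid=grid,
        intensity=np.clip(inten, 0.0, 1.0).reshape(grid.shape),
        mask=(prob >= threshold).reshape(grid.shape).astype(np.uint8),
    )


def plane_grid(axis: str, offset_mm: float, resolution: int,
               extents: tuple, origin: tuple = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Coordinates of an axis-aligned plane raster, shape (res, res, 3).

    ``axis`` names the normal direction ('x' = depth).  ``extents`` is
    (axial_extent_mm, lateral_extent_mm); in-plane axes span their full
    field-of-view range regardless of the acquisition resolution.
    """
    if resolution < 1:
        raise ValueError("resolution must be positive")
    half = extents[1] / 2.0
    spans = {
        "x": (np.linspace(-half, half, resolution),
              np.linspace(-half, half, resolution)),
        "y": (np.linspace(0.0, extents[0], resolution),
              np.linspace(-half, half, resolution)),
        "z": (np.linspace(0.0, extents[0], resolution),
              np.linspace(-half, half, resolution)),
    }
    if axis not in spans:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    u, v = spans[axis]
    if resolution == 1:
        u = np.array([u.mean()])
        v = np.array([v.mean()])
    uu, vv = np.meshgrid(u, v, indexing="ij")
    off = np.full_like(uu, offset_mm)
    comp = {"x": (off, uu, vv), "y": (uu, off, vv), "z": (uu, vv, off)}[axis]
    pts = np.stack(comp, axis=-1)
    return pts + np.asarray(origin)


def oblique_plane_grid(origin_mm, u_axis, v_axis, extent_mm: float,
                       resolution: int) -> np.ndarray:
    """Raster of an arbitrary plane given an orthonormal in-plane frame.

    ``u_axis`` and ``v_axis`` are orthonormal 3-vectors spanning the
    plane; the raster covers ``origin +/- extent/2`` along each.
    Returns (resolution, resolution, 3) world coordinates.
    """
    u = np.asarray(u_axis, dtype=np.float64)
    v = np.asarray(v_axis, dtype=np.float64)
    for vec in (u, v):
        if not np.isclose(np.linalg.norm(vec), 1.0, atol=1e-6):
            raise ValueError("plane axes must be unit vectors")
    if not np.isclose(u @ v, 0.0, atol=1e-6):
        raise ValueError("plane axes must be orthogonal")
    t = np.linspace(-extent_mm / 2.0, extent_mm / 2.0, resolution)
    uu, vv = np.meshgrid(t, t, indexing="ij")
    return (np.asarray(origin_mm, dtype=np.float64)
            + uu[..., None] * u + vv[..., None] * v)


def reslice_oblique(model: InrModel, origin_mm, u_axis, v_axis,
                    extent_mm: float, resolution: int,
                    threshold: float = 0.5) -> tuple:
    """Sample an arbitrary oblique plane; returns (image, mask)."""
    pts = oblique_plane_grid(origin_mm, u_axis, v_axis, extent_mm, resolution)
    inten, prob = evaluate(model, pts.reshape(-1, 3).astype(np.float32))
    shape = pts.shape[:2]
    return (
        np.clip(inten, 0.0, 1.0).reshape(shape),
        (prob >= threshold).reshape(shape).astype(np.uint8),
    )


def reslice(model: InrModel, axis: str, offset_mm: float, resolution: int,
            threshold: float = 0.5) -> tuple:
    """Sample one axis-aligned plane; returns (image, mask).

    The plane may use any resolution, e.g. 16x the acquisition raster;
    the in-plane extent comes from the model's recorded field of view.
    """
    pts = plane_grid(axis, offset_mm, resolution, model.coord_scale)
    inten, prob = evaluate(model, pts.reshape(-1, 3))
    shape = pts.shape[:2]
    return (
        np.clip(inten, 0.0, 1.0).reshape(shape),
        (prob >= threshold).reshape(shape).astype(np.uint8),
    )


def frameset_point_cloud(frames: FrameSet, geom: ScanGeometry | None = None) -> tuple:
    """Flatten a sweep into scattered data: (points_mm, intensity, mask)."""
    geom = geom or frames.geom
    pts = np.concatenate(
        [frame_grid_world(geom, float(a)) for a in frames.angles_deg], axis=0
    )
    return (
        pts.astype(np.float32),
        frames.intensity.reshape(-1).astype(np.float32),
        frames.mask.reshape(-1).astype(np.float32),
    )


class NearestNeighborField:
    """Exact nearest-neighbour interpolant over scattered data.

    Query cost grows with the data size (k-d tree traversal); ties in
    distance are broken toward the lowest datum index, which is made
    deterministic by collapsing duplicate sites to their first
    occurrence.
    """

    def __init__(self, points_mm: np.ndarray, values: np.ndarray):
        points_mm = np.asarray(points_mm, dtype=np.float64)
        values = np.asarray(values)
        if points_mm.ndim != 2 or points_mm.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")
        if len(points_mm) == 0:
            raise ValueError("nearest-neighbour interpolation needs at least one datum")
        if len(values) != len(points_mm):
            raise ValueError("points and values lengths differ")
        uniq, first = np.unique(points_mm, axis=0, return_index=True)
        order = np.sort(first)
        self._points = points_mm[order]
        self._values = values[order]
        self._tree = cKDTree(self._points)

    def __call__(self, queries: np.ndarray) -> np.ndarray:
        q = np.asarray(queries, dtype=np.float64)
        _, idx = self._tree.query(q)
        return self._values[idx]


def nn_interpolate(points_mm: np.ndarray, values: np.ndarray,
                   queries: np.ndarray) -> np.ndarray:
    """One-shot exact nearest-neighbour lookup (see NearestNeighborField)."""
    return NearestNeighborField(points_mm, values)(queries)


def compare_methods(
    model: InrModel,
    frames: FrameSet,
    planes: list,
    truth_mask_fn,
    resolution: int = 256,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-slice Dice/IoU of the INR and the NN baseline vs ground truth.

    ``planes`` is a list of (axis, offset_mm); ``truth_mask_fn`` maps an
    (N, 3) array of world points to the true binary mask values.  Wall
    times are informational only.  Returns a tidy frame with columns
    slice, method, dice, iou, wall_s.
    """
    geom = frames.geom
    pts_data, _, mask_data = frameset_point_cloud(frames, geom)
    nn_field = NearestNeighborField(pts_data, mask_data)
    rows = []
    for axis, off in planes:
        pts = plane_grid(axis, off, resolution,
                         (geom.axial_extent_mm, geom.lateral_extent_mm))
        flat = pts.reshape(-1, 3)
        truth = np.asarray(truth_mask_fn(flat)).astype(np.uint8)

        t0 = time.perf_counter()
        _, prob = evaluate(model, flat)
        inr_mask = (prob >= threshold).astype(np.uint8)
        t_inr = time.perf_counter() - t0

        t0 = time.perf_counter()
        nn_mask = (nn_field(flat) >= 0.5).astype(np.uint8)
        t_nn = time.perf_counter() - t0

        for method, mask, wall in (("inr", inr_mask, t_inr), ("nn", nn_mask, t_nn)):
            rows.append({
                "slice": f"{axis}={off:g}mm",
                "method": method,
                "dice": dice(truth, mask),
                "iou": iou(truth, mask),
                "wall_s": wall,
            })
    return pd.DataFrame.from_records(rows)
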