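"""Synthetic rotating-sweep phantom.

Stands in for a full acoustic acquisition chain: spherical targets with
known contrast are embedded in a uniform background and sliced by the
rotating image plane.  Frames carry first-order B-mode statistics
(piecewise-constant echo amplitude with optional unit-mean Rayleigh
speckle); segmentation masks are rendered noise-free from the geometry,
so reconstruction error can be attributed to the representation rather
than to a segmentation model.  Wave propagation, beamforming,
attenuation and elevation-beam blur are intentionally not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridSpec, ScanGeometry, frame_grid_world

__all__ = [
    "Sphere",
    "SpherePhantom",
    "FrameSet",
    "make_phantom",
    "render_frame",
    "render_sweep",
    "rasterize_ground_truth",
    "sphere_volume_mm3",
    "compress_dynamic_range",
]

# Paper-scale field of view for the simulated experiments (mm).
DEFAULT_AXIAL_EXTENT_MM = 55.0
DEFAULT_LATERAL_EXTENT_MM = 82.0
_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple
    radius_mm: float
    contrast_db: float  # -inf marks an anechoic target
    label: int


@dataclass(frozen=True)
class SpherePhantom:
    """Ground-truth scene: spheres in a uniform speckle background.

    ``speckle_scale`` in [0, 1] blends between a noise-free render (0)
    and fully developed unit-mean Rayleigh speckle (1); the blend keeps
    the mean amplitude of every region equal to its noise-free level.
    """

    spheres: tuple
    background_level: float = 0.5
    speckle_scale: float = 0.0
    axial_extent_mm: float = DEFAULT_AXIAL_EXTENT_MM
    lateral_extent_mm: float = DEFAULT_LATERAL_EXTENT_MM

    def __post_init__(self) -> None:
        if not 0.0 < self.background_level < 1.0:
            raise ValueError("background_level must lie in (0, 1)")
        if not 0.0 <= self.speckle_scale <= 1.0:
            raise ValueError("speckle_scale must lie in [0, 1]")
        labels = [s.label for s in self.spheres]
        if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
            raise ValueError("sphere labels must be unique positive integers")
        for s in self.spheres:
            if s.radius_mm <= 0:
                raise ValueError("sphere radii must be positive")
            if s.contrast_db != -math.inf and not math.isfinite(s.contrast_db):
                raise ValueError("contrast must be finite or -inf (anechoic)")
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1:]:
                d = math.dist(a.center_mm, b.center_mm)
                if d <= a.radius_mm + b.radius_mm:
                    raise ValueError(
                        f"spheres {a.label} and {b.label} overlap"
                    )

    @property
    def extents_mm(self) -> tuple:
        return (self.axial_extent_mm, self.lateral_extent_mm, self.lateral_extent_mm)

    def amplitude_levels(self) -> dict:
        """Noise-free echo amplitude per label (0 = background)."""
        out = {0: self.background_level}
        for s in self.spheres:
            if s.contrast_db == -math.inf:
                out[s.label] = 0.0
            else:
                out[s.label] = self.background_level * 10.0 ** (s.contrast_db / 20.0)
        return out

    def to_dict(self) -> dict:
        return {
            "spheres": [
                {
                    "center_mm": list(s.center_mm),
                    "radius_mm": s.radius_mm,
                    "contrast_db": "anechoic" if s.contrast_db == -math.inf else s.contrast_db,
                    "label": s.label,
                }
                for s in self.spheres
            ],
            "background_level": self.background_level,
            "speckle_scale": self.speckle_scale,
            "axial_extent_mm": self.axial_extent_mm,
            "lateral_extent_mm": self.lateral_extent_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpherePhantom":
        spheres = tuple(
            Sphere(
                center_mm=tuple(s["center_mm"]),
                radius_mm=s["radius_mm"],
                contrast_db=-math.inf if s["contrast_db"] == "anechoic" else s["contrast_db"],
                label=s["label"],
            )
            for s in d["spheres"]
        )
        return cls(
            spheres=spheres,
            background_level=d["background_level"],
            speckle_scale=d["speckle_scale"],
            axial_extent_mm=d["axial_extent_mm"],
            lateral_extent_mm=d["lateral_extent_mm"],
        )


@dataclass
class FrameSet:
    """Ordered sweep frames: intensities in [0, 1], binary masks, geometry."""

    angles_deg: np.ndarray
    intensity: np.ndarray  # (n_frames, rows, cols) float32
    mask: np.ndarray       # (n_frames, rows, cols) uint8 in {0, 1}
    geom: ScanGeometry

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        n = len(self.angles_deg)
        if self.intensity.shape != (n, self.geom.rows, self.geom.cols):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{n} frames of {self.geom.rows}x{self.geom.cols}"
            )
        if self.mask.shape != self.intensity.shape:
            raise ValueError("mask and intensity shapes differ")
        if self.intensity.min() < 0 or self.intensity.max() > 1:
            raise ValueError("intensity must lie in [0, 1]")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be exactly {0, 1}")

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)


def make_phantom(
    seed: int,
    n_spheres: int = 6,
    radius_range_mm: tuple = (4.0, 15.0),
    contrast_range_db: tuple | None = (-2.0, 8.0),
    axial_extent_mm: float = DEFAULT_AXIAL_EXTENT_MM,
    lateral_extent_mm: float = DEFAULT_LATERAL_EXTENT_MM,
    anechoic: bool = False,
    sizes_are_diameters: bool = False,
    background_level: float = 0.5,
    speckle_scale: float = 0.0,
    min_gap_mm: float = 1.0,
) -> SpherePhantom:
    """Draw a reproducible random sphere phantom.

    Radii (or diameters, with ``sizes_are_diameters``) are uniform in
    ``radius_range_mm``; centres are uniform over the interior of the
    cylinder swept by the frames, rejected until spheres fit inside the
    field of view without touching (``min_gap_mm`` clearance).  With
    ``anechoic`` every target is echo-free (contrast -inf), matching the
    volume-estimation experiment; otherwise contrasts are uniform in
    ``contrast_range_db``.
    """
    if n_spheres < 1:
        raise ValueError("n_spheres must be at least 1")
    lo, hi = radius_range_mm
    if lo <= 0 or hi < lo:
        raise ValueError("invalid radius_range_mm")
    rng = np.random.default_rng(seed)
    half = lateral_extent_mm / 2.0
    placed: list[tuple] = []
    attempts = 0
    while len(placed) < n_spheres:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {n_spheres} non-overlapping spheres in "
                f"{attempts - 1} attempts; use fewer or smaller spheres"
            )
        r = rng.uniform(lo, hi)
        if sizes_are_diameters:
            r /= 2.0
        if 2 * r >= min(axial_extent_mm, lateral_extent_mm):
            continue
        cx = rng.uniform(r, axial_extent_mm - r)
        # uniform over the disc of admissible transverse centres
        rho_max = half - r
        if rho_max <= 0:
            continue
        rho = math.sqrt(rng.uniform(0.0, 1.0)) * rho_max
        phi = rng.uniform(0.0, 2.0 * math.pi)
        c = (cx, rho * math.cos(phi), rho * math.sin(phi))
        if all(math.dist(c, pc) > r + pr + min_gap_mm for pc, pr in placed):
            placed.append((c, r))
    if anechoic:
        contrasts = [-math.inf] * n_spheres
    else:
        if contrast_range_db is None:
            raise ValueError("contrast_range_db required unless anechoic")
        contrasts = [rng.uniform(*contrast_range_db) for _ in range(n_spheres)]
    spheres = tuple(
        Sphere(center_mm=c, radius_mm=r, contrast_db=k, label=i + 1)
        for i, ((c, r), k) in enumerate(zip(placed, contrasts))
    )
    return SpherePhantom(
        spheres=spheres,
        background_level=background_level,
        speckle_scale=speckle_scale,
        axial_extent_mm=axial_extent_mm,
        lateral_extent_mm=lateral_extent_mm,
    )


def _labels_at(phantom: SpherePhantom, points_mm: np.ndarray) -> np.ndarray:
    """Sphere label at each point (0 = background); spheres are disjoint."""
    lab = np.zeros(points_mm.shape[0], dtype=np.int32)
    for s in phantom.spheres:
        d2 = ((points_mm - np.asarray(s.center_mm, dtype=points_mm.dtype)) ** 2).sum(axis=1)
        lab[d2 < s.radius_mm ** 2] = s.label
    return lab


def render_frame(
    phantom: SpherePhantom,
    geom: ScanGeometry,
    angle_deg: float,
    noise_seed: int | None = None,
) -> tuple:
    """Render one B-mode-like frame and its exact mask at a sweep angle.

    The noise-free level of a pixel is the amplitude of the region its
    world point falls in (background scaled by 10^(contrast/20) inside a
    sphere, 0 for anechoic targets).  Speckle multiplies the level by a
    unit-mean draw and the result is clipped to [0, 1].  Masks come from
    the analytic geometry and carry no noise.
    """
    angle_mod = float(angle_deg) % 360.0
    pts = frame_grid_world(geom, angle_mod).astype(np.float32)
    labels = _labels_at(phantom, pts)
    levels = phantom.amplitude_levels()
    lut = np.zeros(max(levels) + 1, dtype=np.float32)
    for k, v in levels.items():
        lut[k] = v
    inten = lut[labels]
    if phantom.speckle_scale > 0:
        rng = np.random.default_rng(noise_seed)
        ray = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=inten.shape)
        gain = (1.0 - phantom.speckle_scale) + phantom.speckle_scale * ray
        inten = inten * gain.astype(np.float32)
    inten = np.clip(inten, 0.0, 1.0)
    mask = (labels > 0).astype(np.uint8)
    shape = (geom.rows, geom.cols)
    return inten.reshape(shape), mask.reshape(shape)


def render_sweep(phantom: SpherePhantom, geom: ScanGeometry, seed: int = 0) -> FrameSet:
    """Render the whole sweep; per-frame noise seeds spawn from ``seed``."""
    angles = geom.angles_deg
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(angles))
    frames, masks = [], []
    for ang, child in zip(angles, children):
        i, m = render_frame(phantom, geom, ang,
                            noise_seed=int(child.generate_state(1)[0] % (2 ** 31)))
        frames.append(i)
        masks.append(m)
    return FrameSet(
        angles_deg=angles,
        intensity=np.stack(frames),
        mask=np.stack(masks),
        geom=geom,
    )


def sphere_volume_mm3(radius_mm: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_mm ** 3


def rasterize_ground_truth(phantom: SpherePhantom, grid: GridSpec) -> tuple:
    """Voxelize the phantom onto ``grid``.

    Returns ``(labels, analytic_volumes)`` where ``labels`` is the 3D
    int array of sphere labels at voxel centres and ``analytic_volumes``
    maps each label to its closed-form volume (4/3) pi r^3 in mm^3.
    """
    pts = grid.voxel_centers()
    labels = _labels_at(phantom, pts).reshape(grid.shape)
    volumes = {s.label: sphere_volume_mm3(s.radius_mm) for s in phantom.spheres}
    return labels, volumes


def compress_dynamic_range(image_db: np.ndarray, dr_db: float) -> np.ndarray:
    """Map a dB image onto [0, 1] over a display dynamic range.

    0 dB (peak) maps to 1; values at or below ``-dr_db`` map to 0;
    in between the map is linear: ``clip((img + dr) / dr, 0, 1)``.
    """
    if dr_db <= 0:
        raise ValueError("dr_db must be positive")
    img = np.asarray(image_db, dtype=np.float64)
    return np.clip((img + dr_db) / dr_db, 0.0, 1.0)
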