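"""Voxel-space geometric kernels for straight needle paths.

All distances, lengths and step sizes are world millimetres; anisotropic
voxel spacing is respected everywhere (no operation does bare index
arithmetic).

Collision testing against a structure mask uses an exact voxel ray
traversal (Amanatides–Woo digital differential analyzer in fractional
index space), so the verdict is independent of any sampling step: a path
is collision-free iff the segment passes through no voxel cell of the
mask.  Uniform point sampling at a caller-chosen step is available as an
alternative mode and serves as a refinement oracle in the test suite.

The liver-capsule insertion angle is measured against the tangent plane of
the capsule at the point where the path first enters the liver: 90 deg
means perpendicular insertion (safest), 0 deg means grazing.  The outward
surface normal is the negated gradient of the Gaussian-smoothed mask
indicator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateNormalError,
    EmptyMaskError,
    GeometryError,
    NoCrossingError,
)
from .volume_io import VoxelGrid, world_to_continuous_index

logger = logging.getLogger(__name__)

#: Bisection tolerance for locating the capsule crossing, mm.
CROSSING_TOL_MM = 0.1

#: Default Gaussian scale for surface normals, in multiples of max spacing.
NORMAL_SIGMA_FACTOR = 2.0


@dataclass(frozen=True)
class Segment:
    """Directed straight path from ``p0`` (skin entry) to ``p1`` (target), mm."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]

    def __post_init__(self) -> None:
        p0 = tuple(float(v) for v in np.asarray(self.p0, dtype=float))
        p1 = tuple(float(v) for v in np.asarray(self.p1, dtype=float))
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)
        if self.length <= 0.0:
            raise GeometryError(f"zero-length segment at {p0}")

    @property
    def a(self) -> np.ndarray:
        return np.asarray(self.p0, dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.p1, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from p0 toward p1."""
        d = self.b - self.a
        return d / np.linalg.norm(d)


def sample_segment(seg: Segment, step: float) -> np.ndarray:
    """Evenly spaced points along the segment, both endpoints included.

    Returns ``ceil(length / step) + 1`` points; consecutive samples are at
    most ``step`` mm apart.
    """
    if step <= 0:
        raise GeometryError(f"sampling step must be positive, got {step}")
    n = max(1, int(math.ceil(seg.length / step - 1e-12)))
    t = np.linspace(0.0, 1.0, n + 1)
    return seg.a[None, :] + t[:, None] * (seg.b - seg.a)[None, :]


def default_step_mm(grid: VoxelGrid) -> float:
    """Default sampling step: half the smallest voxel spacing."""
    return 0.5 * float(min(grid.spacing))


# ---------------------------------------------------------------------------
# Exact voxel traversal
# ---------------------------------------------------------------------------

def traverse_voxels(grid: VoxelGrid, seg: Segment) -> Iterator[tuple[int, int, int]]:
    """Yield every in-grid voxel whose cell the segment passes through.

    Voxel ``i`` spans the half-open index interval ``[i-0.5, i+0.5)`` per
    axis (cells centered on voxel centers).  The segment is first clipped
    to the grid box; a segment entirely outside the grid yields nothing.
    """
    shape = np.asarray(grid.shape)
    a = (seg.a - grid.origin_mm) / grid.spacing_mm
    b = (seg.b - grid.origin_mm) / grid.spacing_mm
    d = b - a

    # Liang-Barsky clip to the box [-0.5, shape-0.5] in index space.
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        lo, hi = -0.5, shape[ax] - 0.5
        if abs(d[ax]) < 1e-15:
            if a[ax] < lo or a[ax] > hi:
                return
            continue
        ta = (lo - a[ax]) / d[ax]
        tb = (hi - a[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return

    eps = 1e-9
    p = a + (t0 + eps) * d
    voxel = np.clip(np.rint(p).astype(int), 0, shape - 1)

    step_sign = np.sign(d).astype(int)
    t_next = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if step_sign[ax] > 0:
            boundary = voxel[ax] + 0.5
            t_next[ax] = (boundary - a[ax]) / d[ax]
            t_delta[ax] = 1.0 / d[ax]
        elif step_sign[ax] < 0:
            boundary = voxel[ax] - 0.5
            t_next[ax] = (boundary - a[ax]) / d[ax]
            t_delta[ax] = -1.0 / d[ax]

    t_end = t1
    while True:
        yield tuple(int(v) for v in voxel)
        ax = int(np.argmin(t_next))
        if t_next[ax] > t_end:
            return
        voxel[ax] += step_sign[ax]
        if voxel[ax] < 0 or voxel[ax] >= shape[ax]:
            return
        t_next[ax] += t_delta[ax]


def _points_to_voxels(points: np.ndarray, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Nearest in-grid voxel indices for world points; second array flags in-bounds."""
    idx = np.rint(world_to_continuous_index(points, grid)).astype(int)
    shape = np.asarray(grid.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, inb


def segment_intersects(
    mask: np.ndarray,
    grid: VoxelGrid,
    seg: Segment,
    step: float | None = None,
) -> bool:
    """True iff the segment touches any mask voxel.

    With ``step=None`` (default) the exact voxel traversal decides; with a
    numeric step, points sampled every ``step`` mm are tested against their
    nearest voxel (the historical sampled mode, used as a cross-check).
    A segment entirely outside the grid is non-intersecting (logged).
    """
    if step is None:
        hit = False
        seen = False
        for idx in traverse_voxels(grid, seg):
            seen = True
            if mask[idx]:
                hit = True
                break
        if not seen:
            logger.warning("segment %s-%s entirely outside grid", seg.p0, seg.p1)
        return hit

    points = sample_segment(seg, step)
    idx, inb = _points_to_voxels(points, grid)
    if not inb.any():
        logger.warning("segment %s-%s entirely outside grid", seg.p0, seg.p1)
        return False
    sel = idx[inb]
    return bool(mask[sel[:, 0], sel[:, 1], sel[:, 2]].any())


# ---------------------------------------------------------------------------
# Distance fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceField:
    """Per-voxel world Euclidean distance (mm) to the nearest structure voxel."""

    grid: VoxelGrid
    values: np.ndarray

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world points (clamped at the grid edge)."""
        coords = world_to_continuous_index(points, self.grid).T
        return ndimage.map_coordinates(self.values, coords, order=1, mode="nearest")


def distance_transform(mask: np.ndarray, grid: VoxelGrid) -> DistanceField:
    """Exact anisotropic Euclidean distance to the nearest mask voxel center."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError(
            "distance to an empty structure is undefined; treat it as +infinity "
            "at configuration level"
        )
    values = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return DistanceField(grid=grid, values=values)


def min_distance_along_segment(
    field: DistanceField, seg: Segment, step: float | None = None
) -> float:
    """Minimum interpolated field value over the sampled segment, mm."""
    if step is None:
        step = default_step_mm(field.grid)
    points = sample_segment(seg, step)
    coords = world_to_continuous_index(points, field.grid)
    shape = np.asarray(field.grid.shape)
    inb = np.all((coords > -0.5) & (coords < shape - 0.5), axis=1)
    if not inb.any():
        raise GeometryError("segment does not overlap the distance-field grid")
    return float(max(0.0, field.interpolate(points).min()))


# ---------------------------------------------------------------------------
# Liver capsule: crossing point, surface normal, insertion angle
# ---------------------------------------------------------------------------

def _inside_mask(point: np.ndarray, mask: np.ndarray, grid: VoxelGrid) -> bool:
    idx, inb = _points_to_voxels(point[None, :], grid)
    return bool(inb[0] and mask[tuple(idx[0])])


def capsule_crossing(
    liver_mask: np.ndarray,
    grid: VoxelGrid,
    seg: Segment,
    step: float | None = None,
) -> np.ndarray:
    """World point where the path first enters the liver (p0 -> p1 order).

    The first sampled point inside the liver brackets the crossing, which
    bisection then refines to within 0.1 mm.  A path starting inside the
    liver returns p0 (degenerate, logged).  A path that never enters the
    liver raises :class:`NoCrossingError`.
    """
    if step is None:
        step = default_step_mm(grid)
    points = sample_segment(seg, step)
    inside = np.zeros(len(points), dtype=bool)
    idx, inb = _points_to_voxels(points, grid)
    sel = idx[inb]
    inside[inb] = liver_mask[sel[:, 0], sel[:, 1], sel[:, 2]]

    if inside[0]:
        logger.warning("path entry %s already inside liver; degenerate crossing", seg.p0)
        return seg.a.copy()
    hits = np.flatnonzero(inside)
    if hits.size == 0:
        raise NoCrossingError("segment never enters the liver")
    first = int(hits[0])

    lo = points[first - 1]  # outside
    hi = points[first]      # inside
    while np.linalg.norm(hi - lo) > CROSSING_TOL_MM:
        mid = 0.5 * (lo + hi)
        if _inside_mask(mid, liver_mask, grid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class NormalField:
    """Outward surface normals of a mask from its Gaussian-smoothed indicator.

    Smoothing scale ``sigma`` is in mm (converted per-axis to voxel units);
    the outward normal is the negated, normalized gradient.  Precomputing
    the gradient arrays once makes per-candidate normal queries cheap.
    """

    def __init__(self, mask: np.ndarray, grid: VoxelGrid, sigma: float | None = None):
        if sigma is None:
            sigma = NORMAL_SIGMA_FACTOR * float(max(grid.spacing))
        self.grid = grid
        self.sigma = float(sigma)
        sig_vox = [self.sigma / s for s in grid.spacing]
        smooth = ndimage.gaussian_filter(np.asarray(mask, dtype=float), sigma=sig_vox)
        self._grad = np.gradient(smooth, *grid.spacing)

    def normal_at(self, point: Sequence[float]) -> np.ndarray:
        coords = world_to_continuous_index(np.asarray(point, float), self.grid).T
        g = np.array(
            [ndimage.map_coordinates(gc, coords, order=1, mode="nearest")[0]
             for gc in self._grad]
        )
        norm = np.linalg.norm(g)
        if norm < 1e-12:
            raise DegenerateNormalError(f"vanishing surface gradient at {tuple(point)}")
        return -g / norm  # gradient points into the mask; outward is opposite


def surface_normal(
    mask: np.ndarray, grid: VoxelGrid, point: Sequence[float], sigma: float | None = None
) -> np.ndarray:
    """Outward unit normal of the mask surface at a world point."""
    return NormalField(mask, grid, sigma).normal_at(point)


def angle_from_normal(direction: np.ndarray, normal: np.ndarray) -> float:
    """Insertion angle in degrees in [0, 90]; 90 = perpendicular to the surface.

    Uses |cos| so the result is invariant to the normal's sign convention.
    """
    c = abs(float(np.dot(direction, normal)))
    return math.degrees(math.asin(min(1.0, c)))


def capsule_angle(
    liver_mask: np.ndarray,
    grid: VoxelGrid,
    seg: Segment,
    sigma: float | None = None,
    step: float | None = None,
    normal_field: NormalField | None = None,
) -> float:
    """Angle between the path and the liver capsule's tangent plane, degrees.

    Measured at the point where the path first enters the liver; 90 deg is a
    perpendicular insertion.  Raises NoCrossingError when the path misses
    the liver.
    """
    crossing = capsule_crossing(liver_mask, grid, seg, step=step)
    nf = normal_field or NormalField(liver_mask, grid, sigma)
    normal = nf.normal_at(crossing)
    return angle_from_normal(seg.direction, normal)
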