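"""Synthetic labeled abdominal phantoms with analytic ground truth.

The phantom stands in for a segmented CT study: a closed ellipsoidal skin
shell enclosing an ellipsoidal liver that contains a small spherical tumor
(radius < 15 mm by default, the sub-3-cm-diameter regime the planner is
designed for), plus optional obstacle primitives (sphere / box / cylinder)
playing vessel, bone or lung.  Every structure has a closed-form geometry,
so planner behaviour can be checked against analytic answers; the label
map is what a segmentation pipeline would hand the planner.

Only label maps are produced - no CT intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .volume_io import LabelVolume, VoxelGrid

#: Default label assignment per role.
ROLE_LABELS = {"skin": 1, "liver": 2, "tumor": 3, "vessel": 4, "bone": 5, "lung": 6}


# ---------------------------------------------------------------------------
# Analytic primitives (world mm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, xyz: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        c = self.center
        return ((xyz[0] - c[0]) ** 2 + (xyz[1] - c[1]) ** 2 + (xyz[2] - c[2]) ** 2
                <= self.radius ** 2)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        return c - self.radius, c + self.radius

    def to_dict(self) -> dict:
        return {"kind": "sphere", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class Box:
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def contains(self, xyz) -> np.ndarray:
        out = np.ones_like(xyz[0], dtype=bool)
        for a in range(3):
            out &= (xyz[a] >= self.lower[a]) & (xyz[a] <= self.upper[a])
        return out

    def bounds(self):
        return np.asarray(self.lower, float), np.asarray(self.upper, float)

    def to_dict(self) -> dict:
        return {"kind": "box", "lower": list(self.lower), "upper": list(self.upper)}


@dataclass(frozen=True)
class Cylinder:
    """Finite capped cylinder from axis point p0 to p1."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def contains(self, xyz) -> np.ndarray:
        a = np.asarray(self.p0, float)
        d = np.asarray(self.p1, float) - a
        L2 = float(d @ d)
        rx, ry, rz = (xyz[0] - a[0], xyz[1] - a[1], xyz[2] - a[2])
        t = (rx * d[0] + ry * d[1] + rz * d[2]) / L2
        px = rx - np.clip(t, 0, 1) * d[0]
        py = ry - np.clip(t, 0, 1) * d[1]
        pz = rz - np.clip(t, 0, 1) * d[2]
        radial2 = px ** 2 + py ** 2 + pz ** 2
        return (t >= 0) & (t <= 1) & (radial2 <= self.radius ** 2)

    def bounds(self):
        lo = np.minimum(self.p0, self.p1) - self.radius
        hi = np.maximum(self.p0, self.p1) + self.radius
        return np.asarray(lo, float), np.asarray(hi, float)

    def to_dict(self) -> dict:
        return {"kind": "cylinder", "p0": list(self.p0), "p1": list(self.p1),
                "radius": self.radius}


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, xyz) -> np.ndarray:
        q = np.zeros_like(xyz[0], dtype=float)
        for a in range(3):
            q += ((xyz[a] - self.center[a]) / self.radii[a]) ** 2
        return q <= 1.0

    def bounds(self):
        c = np.asarray(self.center, float)
        r = np.asarray(self.radii, float)
        return c - r, c + r

    def to_dict(self) -> dict:
        return {"kind": "ellipsoid", "center": list(self.center), "radii": list(self.radii)}


Primitive = Sphere | Box | Cylinder | Ellipsoid


# ---------------------------------------------------------------------------
# Phantom configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry of a synthetic study.  Defaults: 64^3 grid at 2 mm spacing
    (12.8 cm cube centered on the origin), skin shell one voxel thick,
    10 mm-radius tumor offset inside the liver, one bone slab and one
    vessel sphere partially obstructing the anterior approach."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] | None = None  # None -> grid centered at 0
    skin: Ellipsoid = field(default_factory=lambda: Ellipsoid((0, 0, 0), (58.0, 54.0, 56.0)))
    shell_voxels: int = 1
    liver: Ellipsoid = field(default_factory=lambda: Ellipsoid((6.0, 0.0, 0.0), (34.0, 28.0, 30.0)))
    tumor: Sphere = field(default_factory=lambda: Sphere((12.0, 4.0, 0.0), 10.0))
    obstacles: tuple[tuple[str, Primitive], ...] = field(
        default_factory=lambda: (
            ("bone", Box((-52.0, -40.0, -10.0), (-40.0, 40.0, 10.0))),
            ("vessel", Sphere((14.0, -20.0, 6.0), 7.0)),
        )
    )
    seed: int = 0
    role_labels: dict[str, int] = field(default_factory=lambda: dict(ROLE_LABELS))

    def grid(self) -> VoxelGrid:
        if self.origin is not None:
            origin = self.origin
        else:
            origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing))
        return VoxelGrid(shape=self.shape, spacing=self.spacing, origin=origin)


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a rasterized phantom."""

    tumor_centroid: tuple[float, float, float]
    obstacles: list[dict]
    liver: dict
    skin: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "tumor_centroid": list(self.tumor_centroid),
            "obstacles": self.obstacles,
            "liver": self.liver,
            "skin": self.skin,
            "seed": self.seed,
        }


def _check_bounds(name: str, prim: Primitive, grid: VoxelGrid) -> None:
    lo, hi = grid.world_bounds()
    plo, phi = prim.bounds()
    if np.any(plo < lo) or np.any(phi > hi):
        raise ConfigurationError(f"{name} primitive extends beyond the grid")


def generate_phantom(config: PhantomConfig) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterize the phantom; deterministic for a fixed config (incl. seed).

    The skin is a closed shell (outer ellipsoid minus its morphological
    erosion), so every ray from outside toward the tumor crosses it.
    Raises ConfigurationError when the tumor is not inside the liver, the
    liver is not inside the skin, or a primitive leaves the grid.
    """
    grid = config.grid()
    xs, ys, zs = grid.axis_coordinates()
    xyz = np.meshgrid(xs, ys, zs, indexing="ij")

    _check_bounds("skin", config.skin, grid)
    _check_bounds("liver", config.liver, grid)
    _check_bounds("tumor", config.tumor, grid)

    body = config.skin.contains(xyz)
    inner = ndimage.binary_erosion(body, iterations=max(1, int(config.shell_voxels)))
    shell = body & ~inner

    liver = config.liver.contains(xyz)
    tumor = config.tumor.contains(xyz)
    if not tumor.any():
        raise ConfigurationError("tumor primitive rasterizes to zero voxels")
    if np.any(tumor & ~liver):
        raise ConfigurationError("tumor is not fully inside the liver")
    if np.any(liver & ~inner):
        raise ConfigurationError("liver is not fully inside the skin shell")

    labels = np.zeros(grid.shape, dtype=np.uint8)
    rl = config.role_labels
    labels[liver] = rl["liver"]
    labels[tumor] = rl["tumor"]
    labels[shell & (labels == 0)] = rl["skin"]

    used_roles = {"skin", "liver", "tumor"}
    obstacle_truth: list[dict] = []
    for role, prim in config.obstacles:
        if role not in rl:
            raise ConfigurationError(f"obstacle role {role!r} has no label assignment")
        _check_bounds(role, prim, grid)
        mask = prim.contains(xyz)
        # vessels run through liver parenchyma; obstacles may claim liver
        # voxels but never the tumor or the skin shell
        paintable = mask & ((labels == 0) | (labels == rl["liver"]))
        if not paintable.any():
            raise ConfigurationError(f"{role!r} obstacle rasterizes to zero voxels")
        labels[paintable] = rl[role]
        used_roles.add(role)
        obstacle_truth.append({"role": role, **prim.to_dict()})

    role_map = {role: (rl[role],) for role in sorted(used_roles)}
    volume = LabelVolume(grid=grid, labels=labels, role_map=role_map)
    truth = PhantomTruth(
        tumor_centroid=tuple(float(v) for v in config.tumor.center),
        obstacles=obstacle_truth,
        liver=config.liver.to_dict(),
        skin=config.skin.to_dict(),
        seed=int(config.seed),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Two-objective screening fixture
# ---------------------------------------------------------------------------

class ScreeningPointset(NamedTuple):
    """A constructed 2-objective candidate set with known Pareto structure."""

    points: np.ndarray          # (n, 2): (distance-to-risk mm, path-length mm)
    reference_index: int        # index of the clinician-chosen point P
    directions: tuple[str, str]  # ("max", "min")


def make_screening_pointset() -> ScreeningPointset:
    """Candidate set whose Pareto structure is known by construction.

    Objectives: distance to the nearest risk structure (maximize) and path
    length (minimize).  Exactly six points are non-dominated, and the
    designated reference point - a stand-in for a clinician's manually
    chosen entry - is dominated by exactly three candidates, the
    screening output shown to the operator.  Coordinates are synthetic;
    only the combinatorial structure matters.
    """
    points = np.array(
        [
            # the six-point trade-off front
            (10.0, 12.0),
            (20.0, 20.0),
            (30.0, 30.0),
            (40.0, 45.0),
            (50.0, 62.0),
            (60.0, 80.0),
            # dominated fillers; (35, 50) also dominates the reference point
            (35.0, 50.0),
            (15.0, 40.0),
            (45.0, 70.0),
            (55.0, 90.0),
            (12.0, 30.0),
            (22.0, 70.0),
            (48.0, 90.0),
            # reference point P: dominated by (30,30), (40,45), (35,50)
            (25.0, 55.0),
        ]
    )
    return ScreeningPointset(points=points, reference_index=13, directions=("max", "min"))
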