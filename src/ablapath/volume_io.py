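"""Labeled-volume I/O and the coordinate contract used by every other module.

Coordinate convention
---------------------
* Arrays are indexed ``labels[i, j, k]`` with axes ``(x, y, z)`` in an
  LPS-oriented world frame (files with other axis-aligned orientations are
  reoriented on read; non-axis-aligned direction matrices are rejected).
* Voxel indices are 0-based.
* The world position of voxel ``(i, j, k)`` is its *center*:
  ``origin + spacing * (i, j, k)`` in millimetres.

Anatomy is addressed through semantic *roles* (skin, liver, tumor, vessel,
bone, lung, ...) rather than raw integer labels; several labels may share a
role (e.g. hepatic and portal vessels both acting as vascular risk
structures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import SimpleITK as sitk

from .errors import BoundsError, ConfigurationError, FormatError, VoxelTypeError

logger = logging.getLogger(__name__)

#: Roles the planner knows about.  "skin", "liver" and "tumor" must be
#: non-empty before planning; the rest are optional risk structures.
KNOWN_ROLES = ("skin", "liver", "tumor", "vessel", "bone", "lung", "other")

#: Roles that must map to at least one present label before planning.
REQUIRED_ROLES = ("skin", "liver", "tumor")

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D grid: shape, anisotropic mm spacing, world origin (LPS)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ConfigurationError(f"grid shape must be three positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"grid spacing must be three positive mm, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_mm(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World extent covered by voxel cells (centers +/- half a voxel)."""
        lo = self.origin_mm - 0.5 * self.spacing_mm
        hi = self.origin_mm + (np.asarray(self.shape) - 0.5) * self.spacing_mm
        return lo, hi

    def contains_world(self, point: Sequence[float]) -> bool:
        lo, hi = self.world_bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )


def voxel_to_world(index: Sequence[int], grid: VoxelGrid) -> np.ndarray:
    """World-mm position of the center of voxel ``index``."""
    idx = np.asarray(index)
    if idx.shape != (3,):
        raise BoundsError(f"index must be a triple, got {index}")
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        raise BoundsError(f"voxel index {tuple(idx)} outside grid shape {grid.shape}")
    return grid.origin_mm + grid.spacing_mm * idx


def world_to_voxel(point: Sequence[float], grid: VoxelGrid) -> tuple[int, int, int]:
    """Nearest voxel index for a world-mm point (inverse of voxel_to_world)."""
    p = np.asarray(point, dtype=float)
    idx = np.rint((p - grid.origin_mm) / grid.spacing_mm).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        raise BoundsError(f"world point {tuple(p)} outside grid")
    return tuple(int(i) for i in idx)


def world_to_continuous_index(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Fractional voxel indices for an (n, 3) array of world points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - grid.origin_mm) / grid.spacing_mm


@dataclass
class LabelVolume:
    """Integer label map on a :class:`VoxelGrid` plus a role -> labels mapping."""

    grid: VoxelGrid
    labels: np.ndarray
    role_map: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind == "b":
            self.labels = self.labels.astype(np.uint8)
        if self.labels.dtype.kind not in "iu":
            raise VoxelTypeError(f"labels must be integer-typed, got {self.labels.dtype}")
        if tuple(self.labels.shape) != self.grid.shape:
            raise ConfigurationError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if self.labels.min(initial=0) < 0:
            raise VoxelTypeError("labels must be non-negative (0 = background)")
        self.role_map = {
            str(role): tuple(int(v) for v in labels)
            for role, labels in self.role_map.items()
        }

    # -- role handling ----------------------------------------------------
    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of all labels assigned to ``role`` (empty role -> all False)."""
        labels = self.role_map.get(role, ())
        if not labels:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.labels, labels)

    def mask_union(self, roles: Iterable[str]) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for role in roles:
            out |= self.mask(role)
        return out

    def role_voxel_counts(self) -> dict[str, int]:
        return {role: int(self.mask(role).sum()) for role in self.role_map}

    def validate_roles(self, required: Sequence[str] = REQUIRED_ROLES) -> None:
        """Check every declared label exists and required roles are non-empty."""
        present = np.unique(self.labels)
        for role, labels in self.role_map.items():
            missing = [v for v in labels if v not in present]
            if missing:
                raise ConfigurationError(
                    f"role {role!r} maps to label(s) {missing} absent from the volume"
                )
        for role in required:
            if not self.role_map.get(role):
                raise ConfigurationError(
                    f"role {role!r} must map to at least one label before planning"
                )


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(suf) for suf in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format {path.name!r}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_label_volume(path, role_map: Mapping[str, Sequence[int]] | None = None) -> LabelVolume:
    """Read a labeled volume (NIfTI / MetaImage / NRRD) and bind roles.

    The image is reoriented to the internal LPS axis-aligned convention; a
    non-axis-aligned direction matrix is rejected.  Declared role labels
    must be present in the voxel data.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on parse failure
        raise FormatError(f"cannot read {path}: {exc}") from exc

    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        img = sitk.DICOMOrient(img, "LPS")
        direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise FormatError(
                f"{path}: non-axis-aligned direction matrix is not supported"
            )

    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.dtype.kind not in "iu":
        raise VoxelTypeError(f"{path}: voxel type {arr.dtype} is not integer")
    labels = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (x, y, z)

    grid = VoxelGrid(
        shape=tuple(int(n) for n in labels.shape),
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )
    volume = LabelVolume(grid=grid, labels=labels, role_map=dict(role_map or {}))
    if role_map:
        present = np.unique(labels)
        for role, vals in volume.role_map.items():
            missing = [v for v in vals if v not in present]
            if missing:
                raise ConfigurationError(
                    f"role {role!r} maps to label(s) {missing} absent from {path.name}"
                )
    return volume


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write a LabelVolume; the result re-reads identically (grid + labels)."""
    path = Path(path)
    _check_suffix(path)
    arr = volume.labels
    if arr.dtype.itemsize > 4:
        arr = arr.astype(np.int32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.grid.origin))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
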