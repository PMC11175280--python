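"""Candidate enumeration and clinical hard constraints.

A candidate path is the straight segment from a skin-surface voxel center
to the tumor center of mass.  Three hard constraints decide admissibility:

* no contact with any risk structure (vessel / bone / lung by default),
* path length strictly below the ablation-needle length,
* liver-capsule insertion angle at or above the clinical threshold
  (a path that never crosses the capsule is rejected outright: the needle
  must traverse liver parenchyma to reach an intrahepatic target).

Candidates that survive carry the three raw soft-constraint values used
for scoring downstream: minimum clearance of the whole path from the risk
structures (mm), path length (mm) and capsule angle (degrees).  Clearance
is measured for the entire path, not just the entry point, via a
distance field over the risk-structure union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import BoundsError, ConfigurationError
from .geometry import (
    DistanceField,
    NormalField,
    Segment,
    angle_from_normal,
    capsule_crossing,
    default_step_mm,
    distance_transform,
    min_distance_along_segment,
    segment_intersects,
)
from .errors import NoCrossingError
from .volume_io import LabelVolume, voxel_to_world, world_to_voxel

logger = logging.getLogger(__name__)

#: Rejection reasons, in the order constraints are checked.
REASON_COLLISION = "collision"
REASON_LENGTH = "length"
REASON_NO_CROSSING = "no_capsule_crossing"
REASON_ANGLE = "angle"
REASON_CLEARANCE = "clearance"
REJECTION_REASONS = (
    REASON_COLLISION,
    REASON_LENGTH,
    REASON_NO_CROSSING,
    REASON_ANGLE,
    REASON_CLEARANCE,
)

DEFAULT_RISK_ROLES = ("vessel", "bone", "lung", "other")


@dataclass
class PlanningConfig:
    """Planner parameters.

    needle_length_mm
        Ablation-needle length L; admissible paths are strictly shorter.
    min_capsule_angle_deg
        Clinical lower bound on the capsule insertion angle (90 deg =
        perpendicular).  The threshold itself is clinic-specific.
    weights
        Soft-constraint weights (clearance, length, angle); renormalized
        to sum to 1.  Default (0.3, 0.4, 0.3).
    step_mm
        Sampling step for distance/crossing queries; default half the
        smallest voxel spacing.
    skin_stride
        Keep every n-th skin voxel when enumerating candidates.
    risk_roles
        Roles treated as forbidden/risk structures.  Liver and tumor are
        never risk structures.
    min_clearance_mm
        Optional hard safety margin; 0 forbids contact only.
    """

    needle_length_mm: float = 150.0
    min_capsule_angle_deg: float = 20.0
    weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    step_mm: float | None = None
    skin_stride: int = 1
    risk_roles: tuple[str, ...] = DEFAULT_RISK_ROLES
    normal_sigma_mm: float | None = None
    min_clearance_mm: float = 0.0
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.needle_length_mm <= 0:
            raise ConfigurationError("needle length must be positive")
        if not 0.0 <= self.min_capsule_angle_deg <= 90.0:
            raise ConfigurationError("capsule-angle threshold must be in [0, 90] deg")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,):
            raise ConfigurationError("exactly three soft-constraint weights required")
        if np.any(w < 0):
            raise ConfigurationError("soft-constraint weights must be non-negative")
        total = float(w.sum())
        if total <= 0:
            raise ConfigurationError("at least one soft-constraint weight must be positive")
        self.weights = tuple(float(v) for v in w / total)
        if int(self.skin_stride) < 1:
            raise ConfigurationError("skin stride must be >= 1")
        self.skin_stride = int(self.skin_stride)
        if self.min_clearance_mm < 0:
            raise ConfigurationError("clearance margin must be non-negative")
        if int(self.top_k) < 1:
            raise ConfigurationError("top_k must be >= 1")
        self.top_k = int(self.top_k)
        for role in ("liver", "tumor", "skin"):
            if role in self.risk_roles:
                raise ConfigurationError(f"{role!r} cannot be a risk structure")

    def to_dict(self) -> dict:
        return {
            "needle_length_mm": self.needle_length_mm,
            "min_capsule_angle_deg": self.min_capsule_angle_deg,
            "weights": list(self.weights),
            "step_mm": self.step_mm,
            "skin_stride": self.skin_stride,
            "risk_roles": list(self.risk_roles),
            "normal_sigma_mm": self.normal_sigma_mm,
            "min_clearance_mm": self.min_clearance_mm,
            "top_k": self.top_k,
        }


@dataclass
class PathCandidate:
    """One entry-to-target path with raw and (later) normalized soft values."""

    entry: tuple[float, float, float]
    target: tuple[float, float, float]
    clearance_mm: float = np.nan     # min world distance of path to risk union
    path_length_mm: float = np.nan
    capsule_angle_deg: float = np.nan
    clearance_score: float | None = None   # each in [0, 10] after normalization
    length_score: float | None = None
    angle_score: float | None = None
    score: float | None = None             # weighted total in [0, 10]
    feasible: bool = False
    rejection: str | None = None
    entry_index: tuple[int, int, int] | None = None

    @property
    def soft_values(self) -> tuple[float, float, float]:
        return (self.clearance_mm, self.path_length_mm, self.capsule_angle_deg)

    def to_dict(self) -> dict:
        return {
            "entry": [float(v) for v in self.entry],
            "target": [float(v) for v in self.target],
            "clearance_mm": float(self.clearance_mm),
            "path_length_mm": float(self.path_length_mm),
            "capsule_angle_deg": float(self.capsule_angle_deg),
            "clearance_score": self.clearance_score,
            "length_score": self.length_score,
            "angle_score": self.angle_score,
            "score": self.score,
            "feasible": bool(self.feasible),
            "rejection": self.rejection,
            "entry_index": list(self.entry_index) if self.entry_index else None,
        }


@dataclass
class FeasibleSet:
    """Candidates surviving every hard constraint, plus rejection provenance."""

    candidates: list[PathCandidate]
    rejections: dict[str, int]
    rejected: list[PathCandidate] = field(default_factory=list)
    volume: LabelVolume | None = None
    config: PlanningConfig | None = None
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.candidates)

    def soft_value_array(self) -> np.ndarray:
        """(n, 3) array of (clearance mm, length mm, angle deg)."""
        return np.array([c.soft_values for c in self.candidates], dtype=float)

    def to_records(self) -> list[dict]:
        return [c.to_dict() for c in self.candidates]


def tumor_target(volume: LabelVolume) -> np.ndarray:
    """Tumor center of mass: unweighted centroid of tumor voxel centers, mm."""
    mask = volume.mask("tumor")
    if not mask.any():
        raise ConfigurationError("tumor role maps to no voxels; cannot define a target")
    _, n_components = ndimage.label(mask)
    if n_components > 1:
        logger.warning(
            "tumor mask has %d connected components; targeting centroid of the union",
            n_components,
        )
    idx = np.argwhere(mask)
    centroid_index = idx.mean(axis=0)
    return volume.grid.origin_mm + volume.grid.spacing_mm * centroid_index


def enumerate_candidates(volume: LabelVolume, config: PlanningConfig) -> list[Segment]:
    """One segment per (stride-decimated) skin voxel, toward the tumor centroid.

    Ordering is deterministic: lexicographic by voxel index, decimated by
    ``config.skin_stride``.
    """
    skin = volume.mask("skin")
    if not skin.any():
        raise ConfigurationError("skin role maps to no voxels; nothing to enumerate")
    target = tumor_target(volume)
    indices = np.argwhere(skin)  # already lexicographic
    indices = indices[:: config.skin_stride]
    segments = []
    for idx in indices:
        entry = volume.grid.origin_mm + volume.grid.spacing_mm * idx
        segments.append(Segment(tuple(entry), tuple(target)))
    return segments


class _PlanningContext:
    """Precomputed masks/fields shared by all candidate evaluations."""

    def __init__(self, volume: LabelVolume, config: PlanningConfig):
        volume.validate_roles()
        self.volume = volume
        self.config = config
        self.grid = volume.grid
        self.step = config.step_mm or default_step_mm(volume.grid)
        self.target = tumor_target(volume)
        # tumor sits inside the liver; include it so the capsule stays closed
        self.liver_mask = volume.mask("liver") | volume.mask("tumor")
        risk_roles = [r for r in config.risk_roles if volume.role_map.get(r)]
        self.risk_mask = volume.mask_union(risk_roles)
        self.risk_field: DistanceField | None = (
            distance_transform(self.risk_mask, self.grid) if self.risk_mask.any() else None
        )
        self.normal_field = NormalField(self.liver_mask, self.grid, config.normal_sigma_mm)

    def evaluate(self, seg: Segment) -> PathCandidate:
        cand = PathCandidate(
            entry=seg.p0,
            target=seg.p1,
            path_length_mm=seg.length,
        )
        try:
            cand.entry_index = world_to_voxel(seg.p0, self.grid)
        except BoundsError:
            cand.entry_index = None

        if segment_intersects(self.risk_mask, self.grid, seg):
            cand.rejection = REASON_COLLISION
            return cand
        if not seg.length < self.config.needle_length_mm:
            cand.rejection = REASON_LENGTH
            return cand
        try:
            crossing = capsule_crossing(self.liver_mask, self.grid, seg, step=self.step)
        except NoCrossingError:
            cand.rejection = REASON_NO_CROSSING
            return cand
        normal = self.normal_field.normal_at(crossing)
        cand.capsule_angle_deg = angle_from_normal(seg.direction, normal)
        if cand.capsule_angle_deg < self.config.min_capsule_angle_deg:
            cand.rejection = REASON_ANGLE
            return cand
        if self.risk_field is not None:
            cand.clearance_mm = min_distance_along_segment(
                self.risk_field, seg, step=self.step
            )
        else:
            cand.clearance_mm = np.inf  # no risk structures configured
        if cand.clearance_mm < self.config.min_clearance_mm:
            cand.rejection = REASON_CLEARANCE
            return cand
        cand.feasible = True
        return cand


def apply_hard_constraints(
    candidates: Sequence[Segment],
    volume: LabelVolume,
    config: PlanningConfig,
    context: _PlanningContext | None = None,
) -> FeasibleSet:
    """Filter candidates by the hard constraints; never raises on emptiness.

    An empty result carries the per-constraint rejection histogram as
    structured diagnostics instead of an exception.
    """
    ctx = context or _PlanningContext(volume, config)
    feasible: list[PathCandidate] = []
    rejected: list[PathCandidate] = []
    rejections = {reason: 0 for reason in REJECTION_REASONS}
    for seg in candidates:
        cand = ctx.evaluate(seg)
        if cand.feasible:
            feasible.append(cand)
        else:
            rejections[cand.rejection] += 1
            rejected.append(cand)
    if not feasible:
        logger.warning("no feasible path; rejections: %s", rejections)
    return FeasibleSet(
        candidates=feasible,
        rejections=rejections,
        rejected=rejected,
        volume=volume,
        config=config,
    )


def plan_feasible_set(volume: LabelVolume, config: PlanningConfig) -> FeasibleSet:
    """Enumerate skin candidates and apply all hard constraints."""
    ctx = _PlanningContext(volume, config)
    segments = enumerate_candidates(volume, config)
    return apply_hard_constraints(segments, volume, config, context=ctx)


def evaluate_user_path(
    entry: Sequence[float],
    volume: LabelVolume,
    config: PlanningConfig,
    context: _PlanningContext | None = None,
) -> PathCandidate:
    """Score a clinician-specified entry point against the same constraints.

    Returns the candidate with its feasibility verdict; an infeasible
    entry is reported, never raised.  Only an entry outside the grid is an
    error.
    """
    entry = np.asarray(entry, dtype=float)
    if not volume.grid.contains_world(entry):
        raise BoundsError(f"entry point {tuple(entry)} outside the volume grid")
    ctx = context or _PlanningContext(volume, config)
    seg = Segment(tuple(entry), tuple(ctx.target))
    return ctx.evaluate(seg)
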