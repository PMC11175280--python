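"""Weighted-sum path scoring and ranking.

Each raw soft-constraint value is min-max normalized over the feasible
set to a 0-10 score with 10 always meaning "best" (largest clearance,
shortest path, largest capsule angle).  The total path score is the
weighted sum of the three sub-scores

    score = w_clearance * clearance_score
          + w_length    * length_score
          + w_angle     * angle_score

with weights renormalized to sum to 1, so the total also lives in
[0, 10]; 10 marks the optimal path under the chosen weighting.  A
criterion whose value is identical across the whole feasible set cannot
discriminate and scores 10 for everyone, which lets a globally dominant
candidate reach the printed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import FeasibleSet, PathCandidate, PlanningConfig
from .errors import ConfigurationError

#: Score assigned when a criterion does not discriminate (max == min).
SCORE_MAX = 10.0


@dataclass(frozen=True)
class SoftScores:
    """Normalized sub-scores, each in [0, 10], larger is always better."""

    clearance: float
    length: float
    angle: float

    def __post_init__(self) -> None:
        for name in ("clearance", "length", "angle"):
            v = getattr(self, name)
            if not 0.0 <= v <= SCORE_MAX:
                raise ConfigurationError(f"{name} score {v} outside [0, {SCORE_MAX}]")


@dataclass
class RankedPlan:
    """Full descending-score ranking plus the recommended top-k."""

    ranking: list[PathCandidate]
    k: int

    @property
    def top(self) -> list[PathCandidate]:
        return self.ranking[: self.k]

    @property
    def optimal(self) -> PathCandidate:
        return self.ranking[0]


def _minmax_scores(values: np.ndarray, larger_is_better: bool) -> np.ndarray:
    """Min-max map to [0, 10]; a non-discriminating criterion scores 10."""
    finite = np.isfinite(values)
    if not finite.all():
        # only the no-risk-structure case produces non-finite values, and
        # then the whole column is +inf -> non-discriminating
        if np.all(np.isposinf(values)):
            return np.full(values.shape, SCORE_MAX)
        raise ConfigurationError("soft values mix finite and non-finite entries")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return np.full(values.shape, SCORE_MAX)
    if larger_is_better:
        ratio = (values - vmin) / (vmax - vmin)
    else:
        ratio = (vmax - values) / (vmax - vmin)
    # the ratio is 1.0 exactly at the optimum; clip guards the half-ulp
    # overshoot floating arithmetic can introduce elsewhere
    return np.clip(SCORE_MAX * ratio, 0.0, SCORE_MAX)


def normalize_soft_scores(feasible: FeasibleSet) -> FeasibleSet:
    """Set the 0-10 sub-scores and weighted totals on every candidate.

    Normalization population is the feasible set itself: scores compare
    admissible paths against each other, not against rejected ones.
    """
    if not feasible.candidates:
        raise ConfigurationError("cannot normalize an empty feasible set")
    if feasible.config is None:
        raise ConfigurationError("feasible set carries no planning config")
    raw = feasible.soft_value_array()
    clearance = _minmax_scores(raw[:, 0], larger_is_better=True)
    length = _minmax_scores(raw[:, 1], larger_is_better=False)
    angle = _minmax_scores(raw[:, 2], larger_is_better=True)
    for i, cand in enumerate(feasible.candidates):
        cand.clearance_score = float(clearance[i])
        cand.length_score = float(length[i])
        cand.angle_score = float(angle[i])
        cand.score = weighted_score(
            SoftScores(cand.clearance_score, cand.length_score, cand.angle_score),
            feasible.config,
        )
    feasible.normalized = True
    return feasible


def weighted_score(ps: SoftScores, config: PlanningConfig) -> float:
    """Weighted sum of the three sub-scores; in [0, 10] for valid inputs."""
    w = np.asarray(config.weights, dtype=float)
    if np.any(w < 0):
        raise ConfigurationError("soft-constraint weights must be non-negative")
    return float(w[0] * ps.clearance + w[1] * ps.length + w[2] * ps.angle)


def _rank_key(cand: PathCandidate):
    # descending score; ties: higher clearance score, shorter path, then
    # lexicographic entry voxel index for full determinism
    return (
        -cand.score,
        -cand.clearance_score,
        cand.path_length_mm,
        cand.entry_index if cand.entry_index is not None else (0, 0, 0),
    )


def rank_paths(feasible: FeasibleSet, config: PlanningConfig, k: int | None = None) -> RankedPlan:
    """Descending-score ranking with a deterministic tie-break.

    ``k`` defaults to the config's top_k (3: the system recommends a
    handful of good paths for the operator to choose from).
    """
    if k is None:
        k = config.top_k
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if not feasible.normalized:
        feasible = normalize_soft_scores(feasible)
    ranking = sorted(feasible.candidates, key=_rank_key)
    return RankedPlan(ranking=ranking, k=int(k))
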