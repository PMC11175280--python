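"""Weight-free path selection by Pareto-front screening.

The three soft objectives - clearance from risk structures (maximize),
path length (minimize) and capsule angle (maximize) - are combined in
pairs; each pair spans a 2D coordinate system in which the exact
non-dominated set is computed by an O(n log n) sort-and-scan.  The global
front is the set intersection of the three pairwise fronts, a weight-free
shortlist.  Candidate q dominates p when q is at least as good in both
objectives of the pair and strictly better in at least one; exact ties
never dominate, and duplicates of a front point are all retained.

Interactive screening: given a clinician-chosen entry point, return every
feasible candidate that dominates it in a chosen objective pair - the
"here are strictly better alternatives" readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constraints import FeasibleSet, PathCandidate, PlanningConfig
from .errors import AblapathError, ConfigurationError
from .planner_weighted import normalize_soft_scores, rank_paths

logger = logging.getLogger(__name__)

MAXIMIZE = "max"
MINIMIZE = "min"

#: Ordered soft objectives: (name, direction).
OBJECTIVES: tuple[tuple[str, str], ...] = (
    ("clearance", MAXIMIZE),
    ("length", MINIMIZE),
    ("angle", MAXIMIZE),
)

#: All unordered objective pairs, deterministic order.
OBJECTIVE_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2))

#: Default interactive pair: path length vs clearance from risk structures.
DEFAULT_PAIR: tuple[int, int] = (0, 1)


class DataError(AblapathError):
    """Non-finite objective values where finite ones are required."""


def _signed(values: np.ndarray, directions) -> np.ndarray:
    """Flip minimized columns so that larger is better everywhere."""
    vals = np.array(values, dtype=float, copy=True)
    for col, direction in enumerate(directions):
        if direction == MINIMIZE:
            vals[:, col] = -vals[:, col]
        elif direction != MAXIMIZE:
            raise ConfigurationError(f"unknown objective direction {direction!r}")
    return vals


def pareto_front_2d(points, directions: tuple[str, str]) -> list[int]:
    """Indices of the exactly non-dominated points of a 2-objective set.

    Sort by the first objective (best first), then scan keeping the best
    second-objective value seen so far; O(n log n).  Duplicated front
    points are all retained.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ConfigurationError("empty point set has no Pareto front")
    if pts.shape[1] != 2:
        raise ConfigurationError(f"expected (n, 2) points, got {pts.shape}")
    if not np.isfinite(pts).all():
        raise DataError("non-finite objective value in Pareto input")
    vals = _signed(pts, directions)

    order = np.lexsort((-vals[:, 1], -vals[:, 0]))  # primary: obj0 desc
    front: list[int] = []
    best_y = -np.inf
    i, n = 0, len(order)
    while i < n:
        j = i
        x = vals[order[i], 0]
        while j < n and vals[order[j], 0] == x:
            j += 1
        group = order[i:j]
        max_y = vals[group[0], 1]  # y sorted descending within the group
        if max_y > best_y:
            front.extend(int(g) for g in group if vals[g, 1] == max_y)
            best_y = max_y
        i = j
    return sorted(front)


@dataclass
class ParetoResult:
    """Pairwise fronts, their intersection, and the empty-intersection fallback."""

    pair_fronts: dict[tuple[str, str], list[int]]
    global_front: list[int]
    fallback: bool = False
    fallback_ranking: list[PathCandidate] | None = None
    candidates: list[PathCandidate] = field(default_factory=list)
    active_objectives: tuple[str, ...] = ()

    def global_candidates(self) -> list[PathCandidate]:
        return [self.candidates[i] for i in self.global_front]

    def to_dict(self) -> dict:
        return {
            "pair_fronts": {"|".join(k): v for k, v in self.pair_fronts.items()},
            "global_front": list(self.global_front),
            "fallback": self.fallback,
            "fallback_ranking": (
                [c.to_dict() for c in self.fallback_ranking]
                if self.fallback_ranking is not None
                else None
            ),
        }


def _objective_matrix(feasible: FeasibleSet) -> np.ndarray:
    vals = feasible.soft_value_array()
    # an absent risk-structure configuration makes clearance +inf for all;
    # a constant column is direction-neutral, so substitute a constant
    for col in range(vals.shape[1]):
        column = vals[:, col]
        if not np.isfinite(column).all():
            if np.all(np.isposinf(column)):
                vals[:, col] = 0.0
            else:
                raise DataError("mixed finite/non-finite objective values")
    return vals


def global_pareto(feasible: FeasibleSet, config: PlanningConfig | None = None) -> ParetoResult:
    """Pairwise fronts over the three objectives, intersected globally.

    An objective that is constant over the whole feasible set cannot
    discriminate between paths; a pair containing it would degenerate to a
    one-objective argmax and over-prune the intersection, so constant
    objectives are excluded from the pairs used for the global front (the
    per-pair fronts of all three pairs are still reported).  When the
    intersection is empty the result is flagged and, if a config is
    available, the weighted-sum top-k is attached as a fallback shortlist.
    """
    if not feasible.candidates:
        raise ConfigurationError("cannot screen an empty feasible set")
    vals = _objective_matrix(feasible)
    names = [name for name, _ in OBJECTIVES]
    dirs = [d for _, d in OBJECTIVES]
    active = [i for i in range(len(names)) if vals[:, i].min() < vals[:, i].max()]

    pair_fronts: dict[tuple[str, str], list[int]] = {}
    front_sets = []
    for a, b in OBJECTIVE_PAIRS:
        front = pareto_front_2d(vals[:, [a, b]], (dirs[a], dirs[b]))
        pair_fronts[(names[a], names[b])] = front
        if a in active and b in active:
            front_sets.append(set(front))

    if front_sets:
        global_front = sorted(set.intersection(*front_sets))
    elif len(active) == 1:  # one discriminating objective: its argmax set
        col = _signed(vals[:, [active[0]]], (dirs[active[0]],))[:, 0]
        global_front = sorted(np.flatnonzero(col == col.max()).tolist())
    else:  # nothing discriminates; every candidate is equally good
        global_front = list(range(len(feasible.candidates)))
    fallback = not global_front
    fallback_ranking = None
    if fallback:
        logger.warning("pairwise Pareto fronts have empty intersection; "
                       "falling back to weighted-sum shortlist")
        cfg = config or feasible.config
        if cfg is not None:
            fallback_ranking = rank_paths(feasible, cfg).top
    return ParetoResult(
        pair_fronts=pair_fronts,
        global_front=global_front,
        fallback=fallback,
        fallback_ranking=fallback_ranking,
        candidates=list(feasible.candidates),
        active_objectives=tuple(names[i] for i in active),
    )


def _dominates(q: np.ndarray, p: np.ndarray) -> bool:
    """Weak-plus-strict domination on larger-is-better values."""
    return bool(np.all(q >= p) and np.any(q > p))


def dominators_of(
    candidate: PathCandidate,
    feasible: FeasibleSet,
    pair: tuple[int, int] = DEFAULT_PAIR,
    config: PlanningConfig | None = None,
) -> list[PathCandidate]:
    """Feasible candidates strictly better than ``candidate`` in the pair.

    ``candidate`` normally comes from ``evaluate_user_path``.  The list is
    sorted by weighted score, best first (the feasible set is normalized
    on demand); the user's own point is never its own dominator.  An
    infeasible user entry still gets screened, with a warning.
    """
    if pair not in OBJECTIVE_PAIRS:
        raise ConfigurationError(f"pair {pair} not one of {OBJECTIVE_PAIRS}")
    if not feasible.candidates:
        raise ConfigurationError("cannot screen against an empty feasible set")
    if not candidate.feasible:
        logger.warning(
            "screening an infeasible entry (%s); dominators still reported",
            candidate.rejection,
        )
    if not feasible.normalized:
        if feasible.config is None and config is not None:
            feasible.config = config
        normalize_soft_scores(feasible)

    dirs = [d for _, d in OBJECTIVES]
    a, b = pair
    vals = _objective_matrix(feasible)[:, [a, b]]
    signed = _signed(vals, (dirs[a], dirs[b]))
    user = np.asarray([candidate.soft_values[a], candidate.soft_values[b]], dtype=float)
    if not np.isfinite(user).all():
        user = np.where(np.isposinf(user), 0.0, user)
    user_signed = _signed(user[None, :], (dirs[a], dirs[b]))[0]

    out = [
        cand
        for cand, row in zip(feasible.candidates, signed)
        if _dominates(row, user_signed)
    ]
    out.sort(key=lambda c: -c.score)
    return out
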