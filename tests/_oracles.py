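"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the naive O(n^2) / dense-sampling formulations and
never call the code paths they verify.
"""

from __future__ import annotations

import numpy as np


def signed_values(points: np.ndarray, directions) -> np.ndarray:
    """Flip minimized columns so larger is better in every column."""
    vals = np.array(points, dtype=float, copy=True)
    for col, d in enumerate(directions):
        if d == "min":
            vals[:, col] = -vals[:, col]
    return vals


def domination_matrix(vals: np.ndarray) -> np.ndarray:
    """dom[q, p] True iff q dominates p (all columns maximize)."""
    ge = (vals[:, None, :] >= vals[None, :, :]).all(axis=-1)
    gt = (vals[:, None, :] > vals[None, :, :]).any(axis=-1)
    return ge & gt


def nondominated_bruteforce(points, directions) -> list[int]:
    """All-pairs non-dominated index set (any number of objectives)."""
    vals = signed_values(np.atleast_2d(points), directions)
    dom = domination_matrix(vals)
    return sorted(np.flatnonzero(~dom.any(axis=0)).tolist())


def dominators_bruteforce(points, directions, p_index: int) -> list[int]:
    """Indices of all points dominating points[p_index]."""
    vals = signed_values(np.atleast_2d(points), directions)
    dom = domination_matrix(vals)
    out = sorted(np.flatnonzero(dom[:, p_index]).tolist())
    return [i for i in out if i != p_index]


def sampled_collision(mask, grid, seg, step: float) -> bool:
    """Dense point-sampling collision verdict (nearest-voxel membership)."""
    from ablapath.geometry import sample_segment

    points = sample_segment(seg, step)
    idx = np.rint((points - grid.origin_mm) / grid.spacing_mm).astype(int)
    shape = np.asarray(grid.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inb.any():
        return False
    sel = idx[inb]
    return bool(np.asarray(mask)[sel[:, 0], sel[:, 1], sel[:, 2]].any())


def nearest_voxel_distance_bruteforce(mask, grid, index) -> float:
    """Distance (mm) from one voxel center to the nearest mask voxel center."""
    targets = np.argwhere(np.asarray(mask, dtype=bool))
    deltas = (targets - np.asarray(index)) * grid.spacing_mm
    return float(np.sqrt((deltas**2).sum(axis=1)).min())
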