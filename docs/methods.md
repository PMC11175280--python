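# Methods

## Problem and model

Percutaneous thermal ablation of small liver tumors (< 3 cm diameter)
requires choosing a straight needle trajectory from a skin entry point to
an intratumoral target. `ablapath` treats trajectory selection as a
constrained multi-objective optimization over a finite candidate set: one
candidate per skin-surface voxel, each the segment from that voxel's
center to the tumor center of mass.

**Hard constraints** (admissibility):

1. the path touches no risk structure (vessel, bone, lung by default);
2. the path length is *strictly* less than the ablation-needle length `L`;
3. the path crosses the liver capsule and meets it at an insertion angle
   at or above a clinical threshold `θ_min`. A path that never crosses
   the capsule is rejected outright — an intrahepatic target must be
   reached through liver parenchyma, and the angle constraint is
   undefined otherwise.

**Soft constraints** (preference), evaluated for each admissible path:

- `S_clearance` — minimum distance (mm) of the *whole path* to the union
  of risk structures. The alternative reading — distance from the entry
  point only — is clinically weaker; the whole-path minimum is what
  endangers the patient and is what we compute.
- `S_length` — path length (mm), shorter is better;
- `S_angle` — capsule insertion angle (degrees), larger is better.

### Weighted-sum selection

Each soft value is min–max normalized over the feasible set onto
`[0, 10]`, direction-aware so that 10 is always best, and combined as

    score = w_c · clearance_score + w_l · length_score + w_a · angle_score

with non-negative weights renormalized to sum to 1 (defaults
`0.3, 0.4, 0.3`). The score therefore lives in `[0, 10]`, with 10 marking
the optimal path under the chosen weighting; a candidate that is
simultaneously best in all three criteria scores exactly 10. The exact
normalization formula and per-subscore range are a design choice inferred
from the printed total range; they are not uniquely determined by the
clinical formulation. Two deliberate details:

- *Normalization population* is the feasible set only. Scores compare
  admissible paths against each other; rejected paths carry no
  preference information.
- *Degenerate criteria* (max = min over the feasible set) score 10 for
  every candidate. Any constant in `[0, 10]` would preserve the ranking;
  10 is chosen so that a globally dominant candidate can reach the
  printed maximum.

Ranking ties break deterministically: higher clearance score, then
shorter path, then lexicographic entry voxel index.

### Pareto selection

Because there is no gold standard for the weights, the planner also
offers weight-free screening. The three objectives are combined in pairs;
in each pair the exact non-dominated set is computed (candidate `q`
dominates `p` when `q` is at least as good in both objectives and
strictly better in at least one; exact ties never dominate; duplicates of
a front point are all retained). The global shortlist is the set
intersection of the pairwise fronts.

Two edge cases the pairwise-intersection rule does not settle by itself:

- **Constant objectives.** An objective constant across the feasible set
  cannot discriminate, but a pair containing it degenerates to a
  one-objective argmax and would prune the intersection to the argmax
  set. Constant objectives are therefore excluded from the pairs used
  for the global intersection (all three pairwise fronts are still
  reported). With one discriminating objective left, the global front is
  its argmax set; with none, every candidate is equally good.
- **Empty intersection.** Pairwise non-domination in all three pairs is
  a strictly stronger requirement than 3-objective Pareto optimality
  (every global-front member is 3-objective optimal, not conversely),
  and with many candidates the intersection is frequently empty. The
  result is then flagged and the weighted-sum top-k attached as a
  fallback shortlist, so the operator always receives a recommendation.

Interactive screening evaluates a clinician-chosen entry point under the
same constraints and returns every feasible candidate that dominates it
in a chosen pair (default: clearance vs. length), sorted by weighted
score — "here are strictly better alternatives".

## Geometric kernels and numerical choices

All geometry is in world millimetres on anisotropic voxel grids; voxel
`(i,j,k)` is centered at `origin + spacing ⊙ (i,j,k)` in an LPS-oriented,
axis-aligned frame (files are reoriented on read).

- **Collision test**: exact voxel ray traversal (Amanatides–Woo DDA in
  fractional index space), not point sampling. Uniform sampling at step
  `s` can miss a voxel whose intersection chord is shorter than `s`;
  with exact traversal, any refinement of a sampled test visits a subset
  of the traversed voxels, so a path accepted as collision-free stays
  collision-free under arbitrarily fine re-checking. Sampled mode (any
  step) remains available and is the refinement oracle in the tests.
- **Distance field**: exact anisotropic Euclidean distance transform
  (`scipy.ndimage.distance_transform_edt` with `sampling=spacing`) to
  the nearest risk-structure voxel center; path clearance is the minimum
  of the trilinearly interpolated field over samples spaced at
  `step = min(spacing)/2` by default.
- **Capsule crossing**: first sampled point inside the liver brackets
  the entry; bisection refines the boundary to 0.1 mm. The liver mask is
  unioned with the tumor mask so the labeled tumor does not punch a hole
  in the parenchyma.
- **Capsule angle**: `90° − angle(direction, outward normal)` at the
  crossing, i.e. the angle to the tangent plane, with 90° meaning
  perpendicular insertion (the safe direction). The reference of the
  angle is a convention choice; it is stated here prominently because
  thresholds only make sense relative to it. The outward normal is the
  negated gradient of the Gaussian-smoothed mask indicator
  (`sigma = 2·max(spacing)` by default, configurable); using `|cos|`
  makes the angle invariant to the normal's sign convention.
- **Degenerate inputs**: a zero-length segment is a geometry error; an
  entry already inside the liver yields a degenerate crossing at the
  entry itself (logged); an empty risk-structure set makes clearance
  `+inf` for every path, which the normalizer treats as a
  non-discriminating criterion.

## Planner parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `needle_length_mm` | 150 | mm | hard strict upper bound on path length (typical ablation needles are 10–20 cm; the value is clinic- and device-specific and deliberately configurable) |
| `min_capsule_angle_deg` | 20 | deg | hard lower bound on the insertion angle; no published consensus value exists, so it is configurable |
| `weights` | 0.3, 0.4, 0.3 | — | soft weights (clearance, length, angle), renormalized to sum 1 |
| `step_mm` | min(spacing)/2 | mm | sampling step for distance/crossing queries |
| `skin_stride` | 1 | — | keep every n-th skin voxel as a candidate |
| `risk_roles` | vessel, bone, lung, other | — | roles forbidden to the path |
| `min_clearance_mm` | 0 | mm | optional hard safety margin (0 = contact only forbidden; distance is otherwise purely a soft criterion) |
| `top_k` | 3 | — | recommended paths (a small shortlist for the operator to choose from) |

## Synthetic phantoms

The phantom generator emulates what a segmentation pipeline hands the
planner: a closed ellipsoidal skin shell (outer ellipsoid minus its
morphological erosion — closure of the shell is what makes the skin the
planner's search space), an ellipsoidal liver containing a spherical
tumor of radius < 15 mm (the sub-3-cm regime the planner targets), and
obstacle primitives (sphere / box / cylinder) labeled vessel, bone or
lung. Obstacles may claim liver voxels (vessels run through parenchyma)
but never tumor or skin. Every structure has closed-form geometry, so
centroids, blocked solid angles and crossing points can be checked
against analytic answers; the ground truth is emitted alongside the
label map. Rasterization is deterministic; the stored seed fixes any
stochastic configuration choices.

What the phantoms do **not** emulate: CT intensities and segmentation
noise, irregular organ shapes, partial-volume label errors, and
respiratory deformation. Passing tests therefore demonstrate the
correctness of the planning mathematics on clean label maps, not
robustness to real segmentation quality.

A separate constructed fixture — a 2-objective candidate set with
exactly six non-dominated points and a designated reference point
dominated by exactly three candidates — pins down the combinatorial
structure of the interactive-screening scenario; its coordinates are
synthetic and only the structure is asserted.

## Problem sizes

Default phantoms are 64³ voxels at 2 mm spacing (tests also use an 88³
aperture phantom whose bone box encloses the liver except for one
window); test plans subsample the skin with strides 5–13, giving
feasible sets of a few hundred to ~2000 candidates. These sizes keep the
full pipeline — enumeration, exact-traversal filtering, distance fields,
normal estimation, ranking and Pareto screening — comfortably
interactive while leaving every code path exercised; stride 1 on a
clinical-resolution volume is the same code, just more candidates.

## Known limitations

- The tumor is abstracted to its center of mass; there is no ablation-
  zone (coagulation) coverage model, no multi-needle planning, and no
  conformality check for irregular tumors.
- No respiratory motion, organ deformation or needle–tissue force model;
  planning is on a static preoperative label map.
- Straight rigid trajectories only.
- The capsule-angle estimate inherits the smoothing scale of the normal
  field; very thin or highly curved liver regions need a smaller
  `normal_sigma_mm`.
- DICOM series are not parsed; volumes must arrive as NIfTI, MetaImage
  or NRRD label maps with an axis-aligned orientation.
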