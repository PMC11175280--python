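# ablapath

Automatic ablation-needle path planning on labeled CT volumes.

Percutaneous thermal ablation destroys a liver tumor by heating it
through a needle inserted from the skin. Choosing the trajectory by hand
is slow and experience-bound, so `ablapath` automates it: given a
segmented abdominal volume (integer label map distinguishing skin,
liver, tumor and risk structures such as vessels, bone and lung), it

1. enumerates candidate paths from skin-surface voxels to the tumor
   center of mass,
2. removes paths violating the clinical **hard constraints** — contact
   with a risk structure, length ≥ needle length `L`, liver-capsule
   insertion angle below a threshold `θ_min`,
3. scores the survivors on three **soft constraints** — clearance from
   risk structures `S_c` (maximize), path length `S_l` (minimize),
   capsule angle `S_a` (maximize) — min–max normalized to `[0, 10]` and
   combined as the weighted sum

   `score = w_c·P_c + w_l·P_l + w_a·P_a`,  default weights `(0.3, 0.4, 0.3)`,

   so 10 marks the optimal path, and
4. alternatively screens paths weight-free by **Pareto optimality**:
   exact non-dominated fronts per objective pair, intersected into a
   global shortlist, plus interactive queries that list every path
   strictly dominating a clinician-chosen entry point.

A built-in phantom generator produces labeled volumes with analytic
ground truth (ellipsoidal skin shell and liver, sub-3-cm spherical
tumor, obstacle primitives), so the whole pipeline is testable without
patient data. Planning runs are archived in a single-file SQLite store
and exportable as JSON/CSV. See `docs/methods.md` for the model,
conventions (e.g. 90° = perpendicular insertion) and numerical choices.

## Worked example

```sh
$ ablapath phantom --out phantom.nii.gz --truth truth.json --seed 1
phantom written to phantom.nii.gz (roles: phantom.roles.json)

$ ablapath plan --volume phantom.nii.gz --roles phantom.roles.json --stride 4 --out plan_out
candidates kept: 1848  rejections: {'collision': 148, 'length': 0, 'no_capsule_crossing': 0, 'angle': 0, 'clearance': 0}
record 1: optimal entry=(29.0, 45.0, -1.0) mm  clearance=19.3 mm  length=44.4 mm  angle=88.5 deg  score=9.68/10
global Pareto front: 0 path(s) (empty intersection; weighted fallback attached)
```

Of 1996 skin entry candidates, 148 were rejected because their path
would cross the phantom's bone slab or vessel; none failed the needle
length (150 mm) or angle (20°) bounds. The recommended path enters at
(29, 45, −1) mm, stays 19.3 mm clear of every risk structure, is 44.4 mm
long and meets the liver capsule at 88.5° (nearly perpendicular); its
weighted score is 9.68 of 10. On this phantom no single path is on all
three pairwise Pareto fronts at once, so the planner flags the empty
intersection and attaches the weighted top-3 as the shortlist — the
documented fallback.

Screening a manually chosen entry point:

```sh
$ ablapath screen --volume phantom.nii.gz --roles phantom.roles.json --stride 4 --entry 40,40,20
user path feasible: clearance=19.3 mm  length=49.8 mm  angle=83.6 deg
336 path(s) dominate the chosen entry in pair clearance:length
  entry=(29.0, 45.0, -1.0) mm  clearance=19.3  length=44.4  angle=88.5  score=9.68
  entry=(25.0, 47.0, -1.0) mm  clearance=19.3  length=44.9  angle=88.9  score=9.65
  entry=(27.0, 47.0, 1.0) mm  clearance=19.3  length=45.6  angle=89.6  score=9.64
```

The chosen entry is admissible but 336 candidates are at least as clear
of risk structures *and* shorter; the top three strictly better
alternatives are printed for the operator.

The same pipeline is available as a library:

```python
from ablapath import (PhantomConfig, PlanningConfig, generate_phantom,
                      plan_feasible_set, rank_paths, global_pareto)

volume, truth = generate_phantom(PhantomConfig(seed=1))
config = PlanningConfig(needle_length_mm=150, min_capsule_angle_deg=20)
feasible = plan_feasible_set(volume, config)
plan = rank_paths(feasible, config)          # plan.optimal, plan.top
pareto = global_pareto(feasible, config)     # pairwise fronts + intersection
```

## Report schemas

`plan` writes `plan_report.json` (full record: volume metadata, config,
ranking with raw values `clearance_mm`, `path_length_mm`,
`capsule_angle_deg`, normalized `*_score` fields and total `score`,
Pareto membership, rejection histogram) and `plan_paths.csv` (one row
per recommended path, full-precision text). The SQLite store holds the
same payload immutably; `ablapath report` re-exports any archived
record.
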