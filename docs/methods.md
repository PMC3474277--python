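# Methods

This note records the model, the parameter choices, the numerical decisions,
and what the synthetic phantoms do and do not establish.

## Coordinate convention

All geometry is computed in physical millimetres in an LPS voxel frame:
array axis 0 grows toward the patient's left (+x), axis 1 toward posterior
(+y), axis 2 toward superior (+z). A voxel's position is its center,
`origin + index * spacing`. Inputs in other orientations are reoriented on
read (SimpleITK `DICOMOrient`), which is metadata-only and idempotent. The
frame makes the anatomical rules literal: the left lung has larger x, upper
lobes larger z, and the right middle lobe — anterior-superior of the lower
lobe on a sagittal view — maximizes (z − y).

## Repulsive force field

Boundary voxels (object voxels with a background voxel in their
6-neighborhood; the grid border counts as background) are point charges.
The force at P from charge C is `(P − C)/‖P − C‖^(m+1)`; the field is the
sum over charges.

* **Order `m = 4`** (default, configurable). Lower orders give smoother
  fields that track only the global tube shape; higher orders follow local
  boundary detail. m = 4 centers well in tubes while averaging away
  single-voxel surface perturbation; the suite asserts the smoothness
  ordering (total variation of field direction along a bent tube is lower
  for m = 2 than m = 4) and the robustness to 1-voxel surface noise.
* **Cutoff radius 25 mm** (default, configurable). Summing only charges
  within 25 mm (k-d tree query) reduces the cost from O(N_P·N_C) to a local
  sum. On a radius-3 mm tube the maximum per-voxel relative deviation from
  the full sum is ~0.1%, far below the 5% envelope the suite enforces. The
  comparison excludes nothing: with the tube axis on half-integer
  coordinates no voxel sits where the field vanishes identically, so the
  relative error is well defined everywhere.
* Charges coincident with the query point are skipped (the law is singular
  at R = 0); an empty neighborhood yields a zero vector with a warning.

## Skeleton extraction

The field pushes interior points onto the medial axis, so a streamline is
seeded at every object voxel center and advected with a fixed step (half
the smallest spacing) along the unit direction of the trilinearly
interpolated field. On the axis consecutive steps reverse; convergence is
declared when the two-step displacement falls below 0.5·step, and the
terminal is the midpoint of the final oscillation pair. Terminals are
quantized to voxels, one skeleton point (mean terminal) per occupied voxel.

Two regularizations deal with the discrete boundary:

* **Wall-patch exclusion.** The exact field *at* a boundary voxel points
  outward on convex walls, because the neighboring surface charges sit
  slightly inside the tangent plane. The advected copy of the field
  therefore subtracts, at boundary voxels only, the contribution of charges
  within 1.9 voxels (the 26-neighborhood ball). Interior voxels keep the
  exact sum, and the stored `ForceField` is everywhere the exact sum.
* **Seed nudge + exit discard.** Boundary seeds start one voxel toward the
  local object mass; streamlines that still leave the object are clamped at
  their last interior position and their terminals discarded (they are not
  sinks), unless nothing else remains.

Two consequences worth knowing. The axis of a *finite* tube is not
uniformly force-free — cap repulsion and wall asymmetry leave a small axial
component — so skeleton terminals retract from tube ends by up to ~1.5
radii, and a streamline started exactly on the axis drifts a few millimetres
to the nearest axial equilibrium rather than standing still. Neither
affects centeredness (max radial deviation on a radius-5 cylinder is ~0.13
voxels) or branch recovery, since terminal branches are much longer than
the retraction. Second, a tube needs roughly **two voxels of radius** to
carry a discrete interior; thinner tubes cannot be centered at all at this
resolution (see Phantoms below).

## Graph construction and branches

The spanning tree over skeleton points is built by the two-move loop:
(1) connect the globally nearest pair between a visited vertex with fewer
than three neighbors and an unvisited point — this join has deliberately no
distance limit, so disconnected fragments (e.g. an interrupted trachea
segmentation) are bridged, with joins >10 mm logged; (2) from the
last-inserted point, greedily chain its nearest unvisited neighbor while
the distance is strictly below the **merge distance, 2 mm** (configurable).
Nearest-pair ties break to the lowest point index; the start vertex is
drawn from a seeded RNG (default seed 0), and on well-separated geometry
the resulting branch decomposition is start-invariant (asserted over 10
seeds). The degree cap of 3 is a modeling choice: anatomical trifurcations
appear as two nearby bifurcations.

Branches are maximal paths between degree≠2 vertices. Before
decomposition, terminal spurs shorter than **3 mm** hanging off bifurcation
points are pruned (shortest first, degrees re-evaluated after each
removal): early-stopping streamline terminals otherwise forge 1–2-point
side twigs that would corrupt the child-selection rules. Genuine terminal
branches are an order of magnitude longer, and the short interior segment
of the abnormal topology (BC) is interior, never pruned.

The trachea is the branch with the largest lumen volume (tie: most superior
endpoint, logged). Its free (degree-1) endpoint is proximal; a breadth-first
walk from its distal endpoint assigns parents, children and generations
(trachea = 0).

## Classification rules and tie-breaks

* Left/right: among the (exactly two, given the degree cap) first-generation
  branches, larger distal x → left main. Fewer than two first-generation
  branches is a hard classification error — the case is reported and
  aborted, since no side assignment is possible.
* "Endpoint" always means the **distal** endpoint, the one away from the
  trachea along the rooted tree.
* LUL/LLL and RUL: the sibling subtree with larger distal z is the upper
  one; an exact z tie breaks to smaller y (more anterior), logged. A main
  bronchus with a single child descends one level, logged; with no
  children, that lung is reported UNLABELED.
* RML/RLL: within the right subtree remaining after RUL removal (rooted at
  node C), E/F are the terminal distal endpoints with maximal/minimal
  (z − y); D is the lowest common ancestor of their branches; the D-child
  subtree containing E is RML, everything else RLL. A remaining subtree
  with fewer than two terminals means the middle-lobe airways are absent
  from the segmentation: everything becomes RLL with a warning, not a
  failure.
* The main bronchi and the bronchus intermedius carry the lower-lobe label
  of their side (left main → LLL, right main and intermedius → RLL): they
  are not inside any lobe anatomically, but a total labeling is required,
  and the lower lobe continues the main axis. The phantom ground truth uses
  the same convention.
* Self-correction: A = carina, B = distal node of the right main, C =
  distal node of the non-RUL child of the right main, with AB and BC the
  Euclidean node distances. Strictly below the **ratio threshold 0.5**
  (configurable) the correction fires: the subtrees branching off at B and
  C are relabeled RUL and the E/F rule is recomputed from the subtree at
  the next node D. At or above the threshold the labels are returned
  unchanged, bit for bit. A missing node C or D skips the correction with a
  log line. The correction is right-lung-specific by design; no symmetric
  left-lung variant is invented.

## Voxel assignment

Each object voxel is assigned to its nearest skeleton point (k-d tree;
distance ties resolve to the lowest skeleton point index) and inherits that
point's branch and lobe. Lumen volume = assigned voxel count × voxel
volume, so branch volumes sum exactly to the mask volume. Euclidean
distance is used as specified — near bifurcations labels can bleed a few
voxels across branches, which is visible in mirror-flip comparisons as a
~20% fringe at junctions while branch-level labels are unaffected.

## Phantoms

The generator emulates what the anatomical rules rely on: a superior
midline trachea (radius 6 mm, the largest lumen by a wide margin), left and
right mains, an upper/lower split per lung, an anterior-superior RML versus
a posterior-inferior RLL, and at least three generations per lobe, on a
128³ grid at 1 mm isotropic spacing. Radii taper ×0.7 per generation,
floored at 2 mm because of the two-voxel resolution limit above. Variants:
`ABNORMAL_SHORT_BC` (upper-lobe branches split across two nodes, geometric
BC/AB ≈ 0.33 — measured ≈ 0.38 after skeletonization — against ≈ 0.9 for
the normal tree), `NO_RML` (right lower path reduced to a chain), and
`MISSING_TRACHEA_PART` (a 6 mm gap splits the mask in two).

`randomize_spec` jitters branch directions (≤15°), lengths and radii
(±20%), resampling until the spec invariants hold again. One invariant is
worth spelling out: a *normal* spec must keep geometric BC/AB ≥ 0.65.
Without it, jitter can push a nominally normal tree into the short-BC
regime, where the (correctly firing) self-correction contradicts the
phantom's own ground truth — the invariant keeps the NORMAL and
ABNORMAL_SHORT_BC conditions disjoint, as their definitions require.
Sibling branches must also separate by more than the sum of their radii
within the shorter branch's length, otherwise no bifurcation exists at
voxel scale to recover.

What phantom tests show: the geometry-driven stages (field, skeleton,
graph, rules, assignment) are correct and robust to surface noise, jitter
and the modeled topology variants. What they do not show: performance on
real CT segmentations, whose airways are curved, irregular in caliber,
subject to segmentation leaks and breaks beyond the modeled gap, and whose
anatomical variability exceeds ±15° jitter. Accuracy numbers from phantoms
are analogues, not estimates, of clinical accuracy.

## Evaluation metric

A structure (trachea or lobe) counts as correct in a phantom run when every
ground-truth branch of that structure has the majority of its voxels
carrying the structure's label. Judging against ground-truth branches
rather than the recovered decomposition keeps junction bleed (above) from
masquerading as labeling error; requiring a per-branch majority is stricter
than a whole-lobe vote.

## Problem sizes

Defaults were chosen so a phantom labels in a few seconds on one CPU
(~10,000 object voxels, ~300 skeleton points, ~19 branches): the
acceptance cohort of 20 randomized phantoms runs in under two minutes, and
the full test suite in a few minutes. All sizes scale with the input; the
pipeline is O(N_P · N_C(25 mm)) in the field stage, which dominates.
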