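# airwaylobes

Lobe-based labeling of segmented airway trees from chest CT.

Regional analysis of airway morphology — wall thickening, lumen narrowing,
branch loss in COPD and other obstructive disease — is most meaningful per
pulmonary lobe, because the five lobes (right upper/middle/lower, left
upper/lower: RUL, RML, RLL, LUL, LLL) are largely independent functional
units. `airwaylobes` takes a **binary airway segmentation** (produced by any
airway segmentation tool; NIfTI, NRRD or MetaImage) and assigns every airway
voxel to the trachea or one of the five lobes, without lobe segmentation and
without matching against a labeled atlas tree.

## Method

Four stages, all in physical millimetres in an LPS frame
(x → patient left, y → posterior, z → superior):

1. **Skeletonization by repulsive force field.** Every boundary voxel acts
   as a point charge; the force a charge C exerts at a point P is

   F⃗(P, C) = (P − C) / ‖P − C‖^(m+1),  with order m = 4,

   and the field at P is the sum over charges — in practice only charges
   within 25 mm, which leaves the field essentially unchanged on tubular
   structures but makes the computation local. Streamlines seeded at every
   object voxel follow the field onto the medial axis; their terminals,
   thinned to one per voxel, are the skeleton points.

2. **Branch identification.** The skeleton points are organized into an
   undirected acyclic graph: repeatedly connect the nearest (visited,
   unvisited) pair — visited vertices being capped at three neighbors — then
   greedily chain nearest unvisited neighbors while the gap is under 2 mm.
   Vertices of degree 1 are terminate points, degree 3 are bifurcation
   points; cutting at bifurcations yields the individual branches. The
   branch with the largest lumen volume is the trachea; rooting there gives
   parent/child relations and generations.

3. **Rule-based classification.** Left vs right by the x of the
   first-generation distal endpoints; LUL vs LLL (and RUL vs the rest) by
   distal z of the second-generation subtrees; RML vs RLL inside the
   remaining right subtree by the sagittal rule that the middle lobe is
   anterior-superior: the terminal endpoint E maximizing (z − y) marks the
   RML, F minimizing (z − y) the RLL, and their lowest common ancestor
   bifurcation D splits the two.

4. **Self-correction.** With A the carina, B the end of the right main
   bronchus and C the next node down the right path, an abnormally short
   BC (BC/AB < 0.5) signals the topology exception in which the upper-lobe
   branches split across B and C; the subtrees branching off at both nodes
   are then relabeled RUL and the RML/RLL rule is recomputed from the next
   node. Finally each airway voxel inherits the lobe of its nearest
   skeleton point, which also yields per-branch lumen volumes.

Clinical masks are not distributed with the package; a phantom generator
produces anatomically plausible bifurcating tube trees (normal, short-BC
abnormal, absent-RML, and interrupted-trachea variants) with per-voxel
ground truth, so the whole pipeline is testable end to end.

## Worked example

```sh
# make a synthetic case with known ground truth, then label it
python -c "
from airwaylobes import phantom
from airwaylobes.volume_io import write_mask
vol, truth = phantom.generate_phantom(phantom.normal_spec())
write_mask(vol, 'case01.nii.gz')"
airwaylobes label case01.nii.gz -o out
```

prints

```
[case01] 19 branches, labels: LLL, LUL, RLL, RML, RUL, TRACHEA
```

and writes `out/case01_lobes.nii.gz` (per-voxel labels), a branch table and
a JSON report. The report for this case reads

```json
{
  "n_object_voxels": 9712,
  "n_skeleton_points": 325,
  "n_branches": 19,
  "branches_per_lobe": {"TRACHEA": 1, "RUL": 3, "RML": 3, "RLL": 5,
                        "LUL": 3, "LLL": 4, "UNLABELED": 0},
  "correction_fired": false
}
```

i.e. the 9,712 airway voxels were skeletonized into 325 centerline points
forming 19 branches, every branch received one of the six labels, and the
topology looked normal so the self-correction left the labels untouched.
The branch table carries, per branch, its parent, generation, length and
lumen volume:

```
branch_id  parent_id  generation label  length_mm  lumen_volume_mm3
        0        3.0           3   RUL      9.278             179.0
        1        3.0           3   RUL      7.334              84.0
        2        5.0           4   RML      7.003             136.0
        3       10.0           2   RUL     19.834             557.0
```

`airwaylobes batch <dir>` labels a directory of masks case by case (one
failure does not stop the batch) and writes a per-lobe summary CSV;
`airwaylobes fixtures <dir>` materializes the standard phantom set.
The classifier rules assume the canonical LPS orientation; the readers
reorient any input with valid orientation metadata automatically.

## Limitations

Lobar, not segmental: branches are named by lobe and generation only, not
by the 32 segmental bronchus names. Tubes need roughly ≥2 voxels of radius
to be resolved as individual branches; see `docs/methods.md` for this and
other numerical details.
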