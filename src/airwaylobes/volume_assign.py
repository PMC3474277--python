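"""Propagation of branch/lobe labels from the skeleton to every airway voxel.

Each object voxel P is assigned to its nearest skeleton point
S* = argmin_i ||P - S_i|| and inherits that point's branch (and hence lobe).
Branch lumen volume is the count of voxels assigned to the branch times the
voxel volume.  Ties in distance are broken by the lowest skeleton point
index, deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .labels import LobeLabel
from .skeletonizer import SkeletonPointSet
from .tree_graph import Branch
from .volume_io import BinaryVolume, LabelVolume

log = logging.getLogger(__name__)

_TIE_EPS = 1e-9


@dataclass
class VoxelAssignment:
    """Nearest-skeleton-point assignment for every object voxel."""

    voxel_indices: np.ndarray  # (N, 3) int, object voxels in argwhere order
    skeleton_index: np.ndarray  # (N,) int, nearest skeleton point per voxel
    branch_id: np.ndarray  # (N,) int, branch of that skeleton point
    volume: BinaryVolume

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def branch_voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.branch_id, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def node_to_branch_map(branches: list[Branch]) -> dict[int, int]:
    """Map each skeleton point (UAG node) to a branch id.

    Junction nodes shared by several branches go to the lowest branch id.
    """
    mapping: dict[int, int] = {}
    for b in sorted(branches, key=lambda b: b.id, reverse=True):
        for n in b.nodes:
            mapping[n] = b.id
    return mapping


def nearest_skeleton_point(
    positions: np.ndarray, skeleton_positions: np.ndarray
) -> np.ndarray:
    """Index of the nearest skeleton point for each query position.

    Exact lowest-index tie-breaking: candidates within `_TIE_EPS` of the
    minimal distance are resolved to the smallest index.
    """
    tree = cKDTree(skeleton_positions)
    k = min(4, len(skeleton_positions))
    d, idx = tree.query(positions, k=k)
    if k == 1:
        return np.atleast_1d(idx)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    tied = d <= (d[:, :1] + _TIE_EPS)
    masked = np.where(tied, idx, np.iinfo(np.int64).max)
    return masked.min(axis=1)


def assign_voxels(
    volume: BinaryVolume,
    points: SkeletonPointSet,
    branches: list[Branch],
) -> VoxelAssignment:
    """Assign every object voxel to its nearest skeleton point's branch and
    fill in the branches' lumen volumes (voxel count x voxel volume)."""
    if points.n_points == 0:
        raise ValueError("cannot assign voxels with an empty skeleton")
    obj_idx = volume.object_indices()
    pts_mm = volume.indices_to_mm(obj_idx)
    nearest = nearest_skeleton_point(pts_mm, points.positions)
    n2b = node_to_branch_map(branches)
    branch_of = np.array([n2b.get(int(i), -1) for i in range(points.n_points)])
    bid = branch_of[nearest]
    assignment = VoxelAssignment(
        voxel_indices=obj_idx, skeleton_index=nearest, branch_id=bid, volume=volume
    )
    counts = assignment.branch_voxel_counts()
    for b in branches:
        b.lumen_volume_mm3 = counts.get(b.id, 0) * volume.voxel_volume
    return assignment


def lumen_volume(branch: Branch, assignment: VoxelAssignment) -> float:
    """Lumen volume of one branch in mm^3."""
    n = int((assignment.branch_id == branch.id).sum())
    return n * assignment.volume.voxel_volume


def label_volume(
    assignment: VoxelAssignment, branch_labels: dict[int, LobeLabel]
) -> LabelVolume:
    """Materialize per-voxel lobe labels from per-branch labels."""
    data = np.zeros(assignment.volume.shape, dtype=np.int16)
    lut_size = int(assignment.branch_id.max()) + 2
    lut = np.full(lut_size, int(LobeLabel.UNLABELED), dtype=np.int16)
    for bid, lab in branch_labels.items():
        if 0 <= bid < lut_size:
            lut[bid] = int(lab)
    codes = lut[np.clip(assignment.branch_id, 0, lut_size - 1)]
    i = assignment.voxel_indices
    data[i[:, 0], i[:, 1], i[:, 2]] = codes
    return LabelVolume(data, assignment.volume.spacing, assignment.volume.origin)


def branch_id_volume(assignment: VoxelAssignment) -> LabelVolume:
    """Per-voxel branch identifiers (background = -1... stored as id+1, 0=bg)."""
    data = np.zeros(assignment.volume.shape, dtype=np.int32)
    i = assignment.voxel_indices
    data[i[:, 0], i[:, 1], i[:, 2]] = assignment.branch_id + 1
    return LabelVolume(data, assignment.volume.spacing, assignment.volume.origin)
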