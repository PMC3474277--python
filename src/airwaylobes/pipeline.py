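"""End-to-end pipeline: mask -> skeleton -> branches -> lobes -> label volume."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import force_field, skeletonizer, tree_graph, volume_assign
from .errors import ClassificationError
from .labels import LobeLabel
from .lobe_classifier import ClassificationResult, classify
from .volume_io import BinaryVolume, LabelVolume, read_mask

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the labeling pipeline.

    m : force-law exponent (dimensionless, default 4)
    cutoff_mm : charge locality radius in mm (default 25)
    merge_mm : greedy-chain distance for the graph build in mm (default 2)
    correction_ratio : BC/AB threshold of the self-correction (default 0.5)
    prune_mm : terminal spur pruning length in mm (default 3)
    seed : RNG seed for the graph's random start point
    """

    m: float = 4.0
    cutoff_mm: float = 25.0
    merge_mm: float = 2.0
    correction_ratio: float = 0.5
    prune_mm: float = 3.0
    step_mm: float | None = None
    max_steps: int = 1000
    seed: int = 0
    apply_correction: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        for name in ("cutoff_mm", "merge_mm", "prune_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.correction_ratio < 1):
            raise ValueError("correction_ratio must be in (0, 1)")


@dataclass
class PipelineResult:
    """Outputs of one labeling run."""

    label_volume: LabelVolume
    branch_table: pd.DataFrame
    report: dict
    classification: ClassificationResult
    tree: tree_graph.BranchTree
    skeleton: skeletonizer.SkeletonPointSet
    assignment: volume_assign.VoxelAssignment


def run_label(
    mask: BinaryVolume | str | Path, config: PipelineConfig | None = None
) -> PipelineResult:
    """Label every airway voxel of a binary mask by pulmonary lobe.

    Runs skeletonization (repulsive force field + streamlines), graph/branch
    decomposition, rule-based classification with self-correction, and
    nearest-skeleton-point voxel assignment.  Raises
    :class:`ClassificationError` when the anatomical rules are inapplicable
    (e.g. the carina is missing).
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    volume = read_mask(mask) if isinstance(mask, (str, Path)) else mask

    t0 = time.perf_counter()
    field_ = force_field.compute_field(volume, m=config.m, cutoff_mm=config.cutoff_mm)
    timings["force_field_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    skeleton = skeletonizer.extract_skeleton(
        field_, volume, step=config.step_mm, max_steps=config.max_steps
    )
    timings["skeleton_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    graph = tree_graph.build_uag(skeleton, merge_mm=config.merge_mm, seed=config.seed)
    graph = tree_graph.prune_short_terminal_branches(graph, config.prune_mm)
    branches = tree_graph.decompose_branches(graph)
    timings["graph_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    # restrict the skeleton to the surviving graph nodes before assignment
    kept = sorted(graph.nodes)
    remap = {old: new for new, old in enumerate(kept)}
    skeleton = skeletonizer.SkeletonPointSet(
        positions=skeleton.positions[kept],
        voxel_indices=skeleton.voxel_indices[kept],
        source_volume=volume,
    )
    for b in branches:
        b.nodes = [remap[n] for n in b.nodes]
    import networkx as nx

    graph = nx.relabel_nodes(graph, remap, copy=True)
    assignment = volume_assign.assign_voxels(volume, skeleton, branches)
    timings["assignment_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trachea = tree_graph.find_trachea(branches, graph)
    tree = tree_graph.build_branch_tree(graph, branches, trachea)
    result = classify(
        tree,
        ratio_threshold=config.correction_ratio,
        apply_correction=config.apply_correction,
    )
    for b in branches:
        b.label = result.labels[b.id]
    timings["classify_s"] = time.perf_counter() - t0

    labels_vol = volume_assign.label_volume(assignment, result.labels)
    branch_table = _branch_table(tree, branches)
    per_lobe = {
        lab.name: int(sum(1 for b in branches if b.label == lab)) for lab in LobeLabel
        if lab not in (LobeLabel.BACKGROUND,)
    }
    report = {
        "n_object_voxels": volume.n_object,
        "n_skeleton_points": skeleton.n_points,
        "n_branches": len(branches),
        "branches_per_lobe": per_lobe,
        "labels_present": sorted(
            {b.label.name for b in branches}
        ),
        "correction_fired": result.correction_fired,
        "warnings": list(result.warnings),
        "landmarks": result.landmarks,
        "parameters": {
            "m": config.m,
            "cutoff_mm": config.cutoff_mm,
            "merge_mm": config.merge_mm,
            "correction_ratio": config.correction_ratio,
            "prune_mm": config.prune_mm,
            "seed": config.seed,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return PipelineResult(
        label_volume=labels_vol,
        branch_table=branch_table,
        report=report,
        classification=result,
        tree=tree,
        skeleton=skeleton,
        assignment=assignment,
    )


def _branch_table(tree: tree_graph.BranchTree, branches: list[tree_graph.Branch]) -> pd.DataFrame:
    rows = []
    for b in sorted(branches, key=lambda b: b.id):
        u, v = b.endpoints
        pu, pv = tree.node_pos(u), tree.node_pos(v)
        rows.append(
            {
                "branch_id": b.id,
                "parent_id": tree.parent.get(b.id),
                "generation": tree.generation.get(b.id, -1),
                "label": b.label.name,
                "length_mm": round(b.length_mm, 3),
                "lumen_volume_mm3": b.lumen_volume_mm3,
                "end1_x": round(float(pu[0]), 2),
                "end1_y": round(float(pu[1]), 2),
                "end1_z": round(float(pu[2]), 2),
                "end2_x": round(float(pv[0]), 2),
                "end2_y": round(float(pv[1]), 2),
                "end2_z": round(float(pv[2]), 2),
            }
        )
    return pd.DataFrame(rows)


def per_lobe_summary(result: PipelineResult) -> pd.DataFrame:
    """Branch count, total length and lumen volume per lobe."""
    df = result.branch_table
    return (
        df.groupby("label")
        .agg(
            n_branches=("branch_id", "count"),
            total_length_mm=("length_mm", "sum"),
            total_lumen_mm3=("lumen_volume_mm3", "sum"),
        )
        .reset_index()
    )
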