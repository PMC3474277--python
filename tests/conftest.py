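"""Shared fixtures: small geometric volumes and phantom pipelines.

Expensive end-to-end artifacts are session-scoped so the suite builds each
phantom and runs the pipeline once.
"""

from __future__ import annotations

import numpy as np
import pytest

from airwaylobes import force_field, phantom, pipeline, skeletonizer
from airwaylobes.volume_io import BinaryVolume


def make_cylinder(
    radius: float = 5.0,
    length: int = 60,
    pad: int = 5,
    side: int | None = None,
) -> tuple[BinaryVolume, float, float]:
    """Digital cylinder along z; returns (volume, axis_x, axis_y).

    The axis sits on half-integer coordinates so no voxel center lies
    exactly on it (where the field vanishes identically).
    """
    side = side or int(2 * radius + 12)
    nz = length + 2 * pad
    ax = ay = side // 2 - 0.5
    X, Y, Z = np.meshgrid(np.arange(side), np.arange(side), np.arange(nz), indexing="ij")
    data = ((X - ax) ** 2 + (Y - ay) ** 2 <= radius**2) & (Z >= pad) & (Z < pad + length)
    return BinaryVolume(data), ax, ay


@pytest.fixture(scope="session")
def cylinder():
    vol, ax, ay = make_cylinder()
    return vol, ax, ay


@pytest.fixture(scope="session")
def cylinder_field(cylinder):
    vol, _, _ = cylinder
    return force_field.compute_field(vol)


@pytest.fixture(scope="session")
def cylinder_skeleton(cylinder, cylinder_field):
    vol, _, _ = cylinder
    return skeletonizer.extract_skeleton(cylinder_field, vol)


@pytest.fixture(scope="session")
def normal_phantom():
    spec = phantom.normal_spec()
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def normal_result(normal_phantom):
    _, vol, _ = normal_phantom
    return pipeline.run_label(vol)


@pytest.fixture(scope="session")
def abnormal_phantom():
    spec = phantom.abnormal_short_bc_spec()
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


def branch_accuracy(result, truth) -> tuple[int, int, list]:
    """Per ground-truth branch: does the majority of its voxels carry the
    branch's true lobe label?

    Judging against the known branches (rather than the recovered
    decomposition) keeps junction bleed — nearest-point assignment near
    bifurcations — from masquerading as labeling errors.
    """
    import collections

    from airwaylobes.labels import LobeLabel

    assigned = result.label_volume.data
    ok, tot, mismatches = 0, 0, []
    for bid, row in truth.table.iterrows():
        vox = np.argwhere(truth.branch_id == bid)
        if len(vox) == 0:
            continue
        maj = collections.Counter(
            assigned[vox[:, 0], vox[:, 1], vox[:, 2]].tolist()
        ).most_common(1)[0][0]
        want = int(LobeLabel[row["lobe"]])
        tot += 1
        if maj == want:
            ok += 1
        else:
            mismatches.append((row["branch"], row["lobe"], LobeLabel(maj).name))
    return ok, tot, mismatches


def nearest_point_oracle(queries: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-point search with lowest-index tie resolution."""
    d = np.linalg.norm(queries[:, None, :] - points[None], axis=2)
    dmin = d.min(axis=1, keepdims=True)
    tied = d <= dmin + 1e-9
    return np.where(tied, np.arange(len(points))[None], len(points)).min(axis=1)


def brute_force_field_oracle(volume: BinaryVolume, m: float) -> np.ndarray:
    """Independent all-charges double-loop evaluation of the force sum."""
    charges = []
    data = volume.data
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not data[i, j, k]:
                    continue
                nbrs = [
                    (i - 1, j, k), (i + 1, j, k), (i, j - 1, k),
                    (i, j + 1, k), (i, j, k - 1), (i, j, k + 1),
                ]
                for a, b, c in nbrs:
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not data[a, b, c]:
                        charges.append((i, j, k))
                        break
    charges_mm = volume.indices_to_mm(np.array(charges))
    out = []
    for idx in volume.object_indices():
        p = volume.indices_to_mm(idx)
        f = np.zeros(3)
        for c in charges_mm:
            d = p - c
            r = float(np.sqrt((d * d).sum()))
            if r < 1e-12:
                continue
            f += d * r ** (-(m + 1.0))
        out.append(f)
    return np.array(out)
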