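"""Synthetic airway-tree phantoms with per-voxel ground truth.

A phantom is a union of cylindrical tubes around straight centerline
segments arranged as an anatomically plausible bifurcating tree in the
canonical LPS frame: trachea superior on the midline, left/right main
bronchi, upper/lower lobar subtrees on the left, and upper/middle/lower
subtrees on the right, with tube radii tapering by ~0.7 per generation from
a 6 mm trachea, floored at 2 mm: a tube needs at least two voxels of radius
on the default 1 mm grid to carry a discrete interior for the skeletonizer.  Each branch carries its ground-truth lobe label, and every
object voxel records the branch whose tube it belongs to (overlap near
junctions resolved by smallest distance/radius), so every pipeline stage can
be validated without clinical data.

Topology variants
-----------------
NORMAL              the standard five-lobe tree (>= 3 generations per lobe)
ABNORMAL_SHORT_BC   the upper-lobe branches split across two closely spaced
                    right-sided nodes B and C with BC/AB < 0.5, the topology
                    exception the self-correction targets
NO_RML              the middle-lobe airways are absent and the right lower
                    path is a plain chain (the classifier must warn, not fail)
MISSING_TRACHEA_PART  a gap in the trachea splits the mask into two
                    connected components (exercises fragment joining)
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import PhantomSpecError
from .labels import LobeLabel
from .volume_io import BinaryVolume

log = logging.getLogger(__name__)


class Topology(Enum):
    NORMAL = "NORMAL"
    ABNORMAL_SHORT_BC = "ABNORMAL_SHORT_BC"
    NO_RML = "NO_RML"
    MISSING_TRACHEA_PART = "MISSING_TRACHEA_PART"


@dataclass
class PhantomBranch:
    """One straight tube segment: direction and length relative to the
    parent's distal end."""

    name: str
    parent: str | None
    direction: tuple[float, float, float]
    length_mm: float
    radius_mm: float
    lobe: LobeLabel

    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise PhantomSpecError(f"branch {self.name} has zero direction")
        return d / n


@dataclass
class PhantomSpec:
    """Full phantom description (grid, branch geometry, variant, noise)."""

    branches: list[PhantomBranch]
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    root_anchor_mm: tuple[float, float, float] = (64.0, 64.0, 120.0)
    topology: Topology = Topology.NORMAL
    noise_amplitude_voxels: int = 0
    noise_fraction: float = 0.2
    seed: int = 0
    trachea_gap_mm: tuple[float, float] | None = None  # z-range of the gap

    def branch(self, name: str) -> PhantomBranch:
        for b in self.branches:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Per-voxel and per-branch ground truth accompanying a phantom mask."""

    branch_id: np.ndarray  # (nx,ny,nz) int; -1 = background
    table: pd.DataFrame  # name, parent, lobe, start/end mm, radius, generation
    spec: PhantomSpec

    def lobe_id(self) -> np.ndarray:
        """Per-voxel ground-truth lobe code (0 = background)."""
        lut = np.zeros(len(self.table) + 1, dtype=np.int16)
        for i, row in self.table.iterrows():
            lut[i + 1] = int(LobeLabel[row["lobe"]])
        return lut[self.branch_id + 1]


# ---------------------------------------------------------------------------
# canonical specs


def _base_left() -> list[PhantomBranch]:
    L = LobeLabel
    return [
        PhantomBranch("L_main", "trachea", (20, 0, -8), 21.5, 4.2, L.LLL),
        PhantomBranch("LUL", "L_main", (10, -6, 14), 18.0, 2.9, L.LUL),
        PhantomBranch("LUL_a", "LUL", (8, -4, 8), 12.0, 2.0, L.LUL),
        PhantomBranch("LUL_b", "LUL", (10, 4, -4), 11.0, 2.0, L.LUL),
        PhantomBranch("LLL", "L_main", (8, 6, -18), 21.0, 2.9, L.LLL),
        PhantomBranch("LLL_a", "LLL", (8, 4, -12), 15.0, 2.0, L.LLL),
        PhantomBranch("LLL_b", "LLL", (-6, 6, -12), 15.0, 2.0, L.LLL),
    ]


def _right_lower(parent: str) -> list[PhantomBranch]:
    # generation-4 radii sit at the 2 mm taper floor (see module docstring)
    L = LobeLabel
    return [
        PhantomBranch("RML", parent, (-6, -12, 6), 15.0, 2.0, L.RML),
        PhantomBranch("RML_a", "RML", (-6, -6, 6), 10.0, 2.0, L.RML),
        PhantomBranch("RML_b", "RML", (-2, -10, -2), 9.0, 2.0, L.RML),
        PhantomBranch("RLL_stem", parent, (4, 8, -12), 15.0, 2.0, L.RLL),
        PhantomBranch("RLL_a", "RLL_stem", (6, 6, -10), 13.0, 2.0, L.RLL),
        PhantomBranch("RLL_b", "RLL_stem", (-6, 4, -10), 12.0, 2.0, L.RLL),
    ]


def normal_spec(seed: int = 0, noise_amplitude_voxels: int = 0) -> PhantomSpec:
    """The standard five-lobe phantom."""
    L = LobeLabel
    branches = [
        PhantomBranch("trachea", None, (0, 0, -1), 30.0, 6.0, L.TRACHEA),
        *_base_left(),
        PhantomBranch("R_main", "trachea", (-18, 0, -8), 19.7, 4.2, L.RLL),
        PhantomBranch("RUL", "R_main", (-10, -4, 12), 16.0, 2.9, L.RUL),
        PhantomBranch("RUL_a", "RUL", (-8, -4, 8), 12.0, 2.0, L.RUL),
        PhantomBranch("RUL_b", "RUL", (-6, 4, 4), 9.0, 2.0, L.RUL),
        PhantomBranch("intermedius", "R_main", (-2, 0, -12), 16.0, 2.9, L.RLL),
        *_right_lower("intermedius"),
    ]
    return PhantomSpec(branches=branches, topology=Topology.NORMAL, seed=seed,
                       noise_amplitude_voxels=noise_amplitude_voxels)


def abnormal_short_bc_spec(seed: int = 0) -> PhantomSpec:
    """Right upper lobe split across two closely spaced nodes (BC/AB < 0.5)."""
    L = LobeLabel
    branches = [
        PhantomBranch("trachea", None, (0, 0, -1), 30.0, 6.0, L.TRACHEA),
        *_base_left(),
        PhantomBranch("R_main", "trachea", (-18, 0, -8), 24.0, 4.2, L.RLL),
        PhantomBranch("RUL1", "R_main", (-10, -4, 12), 14.0, 2.9, L.RUL),
        PhantomBranch("RUL1_a", "RUL1", (-8, -4, 8), 10.0, 2.0, L.RUL),
        PhantomBranch("BC_seg", "R_main", (-2, 0, -12), 8.0, 2.9, L.RLL),
        PhantomBranch("RUL2", "BC_seg", (-6, -10, 8), 11.0, 2.0, L.RUL),
        PhantomBranch("CD_seg", "BC_seg", (-2, 0, -12), 9.0, 2.9, L.RLL),
        *_right_lower("CD_seg"),
    ]
    return PhantomSpec(branches=branches, topology=Topology.ABNORMAL_SHORT_BC, seed=seed)


def no_rml_spec(seed: int = 0) -> PhantomSpec:
    """Middle-lobe airways absent: the right lower path is a plain chain."""
    L = LobeLabel
    branches = [
        PhantomBranch("trachea", None, (0, 0, -1), 30.0, 6.0, L.TRACHEA),
        *_base_left(),
        PhantomBranch("R_main", "trachea", (-18, 0, -8), 19.7, 4.2, L.RLL),
        PhantomBranch("RUL", "R_main", (-10, -4, 12), 16.0, 2.9, L.RUL),
        PhantomBranch("RUL_a", "RUL", (-8, -4, 8), 12.0, 2.0, L.RUL),
        PhantomBranch("RUL_b", "RUL", (-6, 4, 4), 9.0, 2.0, L.RUL),
        PhantomBranch("intermedius", "R_main", (-2, 0, -12), 16.0, 2.9, L.RLL),
        PhantomBranch("RLL_stem", "intermedius", (2, 6, -16), 20.0, 2.0, L.RLL),
    ]
    return PhantomSpec(branches=branches, topology=Topology.NO_RML, seed=seed)


def missing_trachea_spec(seed: int = 0) -> PhantomSpec:
    """Normal tree with a 6 mm gap cut out of the trachea."""
    spec = normal_spec(seed=seed)
    return dataclasses.replace(
        spec, topology=Topology.MISSING_TRACHEA_PART, trachea_gap_mm=(104.0, 110.0)
    )


# ---------------------------------------------------------------------------
# geometry


def build_segments(spec: PhantomSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Resolve every branch to absolute (start_mm, end_mm) segments."""
    segs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    anchor = np.asarray(spec.root_anchor_mm, dtype=float)
    pending = list(spec.branches)
    guard = 0
    while pending:
        guard += 1
        if guard > 10000:
            raise PhantomSpecError("branch parent references do not resolve")
        b = pending.pop(0)
        if b.parent is None:
            start = anchor
        elif b.parent in segs:
            start = segs[b.parent][1]
        else:
            pending.append(b)
            continue
        segs[b.name] = (start, start + b.unit_direction() * b.length_mm)
    return segs


def generations(spec: PhantomSpec) -> dict[str, int]:
    gen: dict[str, int] = {}
    pending = list(spec.branches)
    while pending:
        b = pending.pop(0)
        if b.parent is None:
            gen[b.name] = 0
        elif b.parent in gen:
            gen[b.name] = gen[b.parent] + 1
        else:
            pending.append(b)
    return gen


def _terminal_names(spec: PhantomSpec) -> list[str]:
    parents = {b.parent for b in spec.branches if b.parent}
    return [b.name for b in spec.branches if b.name not in parents]


def check_spec(spec: PhantomSpec) -> None:
    """Validate the spec's geometric invariants; raises PhantomSpecError."""
    segs = build_segments(spec)
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    extent = (shape - 1) * spacing
    for b in spec.branches:
        s, e = segs[b.name]
        for p in (s, e):
            if np.any(p - b.radius_mm < 0) or np.any(p + b.radius_mm > extent):
                raise PhantomSpecError(f"branch {b.name} exceeds the grid")

    by_lobe: dict[LobeLabel, list[str]] = {}
    for b in spec.branches:
        by_lobe.setdefault(b.lobe, []).append(b.name)

    max_r = max(b.radius_mm for b in spec.branches)
    left = [n for lob in (LobeLabel.LUL, LobeLabel.LLL) for n in by_lobe.get(lob, [])]
    right = [
        n
        for lob in (LobeLabel.RUL, LobeLabel.RML, LobeLabel.RLL)
        for n in by_lobe.get(lob, [])
        if not spec.branch(n).name.endswith("_main")
    ]
    if left and right:
        min_left_x = min(min(segs[n][0][0], segs[n][1][0]) for n in left if n != "L_main")
        max_right_x = max(max(segs[n][0][0], segs[n][1][0]) for n in right if n != "R_main")
        if min_left_x - max_right_x < 4 * max_r:
            raise PhantomSpecError("left/right x separation below 4x max radius")

    # upper lobes must be superior to their siblings, RML anterior-superior to RLL
    if spec.topology in (Topology.NORMAL, Topology.MISSING_TRACHEA_PART):
        if segs["LUL"][1][2] <= segs["LLL"][1][2]:
            raise PhantomSpecError("LUL distal z must exceed LLL distal z")
        if segs["RUL"][1][2] <= segs["intermedius"][1][2]:
            raise PhantomSpecError("RUL distal z must exceed the intermedius distal z")
    if LobeLabel.RML in by_lobe and LobeLabel.RLL in by_lobe:
        terminals = set(_terminal_names(spec))
        rml_zy = [
            segs[n][1][2] - segs[n][1][1] for n in by_lobe[LobeLabel.RML] if n in terminals
        ]
        rll_zy = [
            segs[n][1][2] - segs[n][1][1] for n in by_lobe[LobeLabel.RLL] if n in terminals
        ]
        if rml_zy and rll_zy and min(rml_zy) <= max(rll_zy):
            raise PhantomSpecError("RML terminal (z-y) must exceed all RLL terminals")
    if spec.topology is Topology.ABNORMAL_SHORT_BC:
        ab = np.linalg.norm(segs["R_main"][1] - segs["R_main"][0])
        bc = np.linalg.norm(segs["BC_seg"][1] - segs["BC_seg"][0])
        if bc / ab >= 0.5:
            raise PhantomSpecError("ABNORMAL_SHORT_BC requires BC/AB < 0.5")
    elif "intermedius" in {b.name for b in spec.branches}:
        # a normal-topology tree must stay clearly out of the short-BC regime,
        # otherwise its own ground truth contradicts the topology definition
        ab = np.linalg.norm(segs["R_main"][1] - segs["R_main"][0])
        bc = np.linalg.norm(segs["intermedius"][1] - segs["intermedius"][0])
        if bc / ab < 0.65:
            raise PhantomSpecError("normal topology requires BC/AB >= 0.65")

    # sibling tubes must separate before the shorter one ends, otherwise no
    # bifurcation is resolvable at voxel scale
    kids_of: dict[str, list[PhantomBranch]] = {}
    for b in spec.branches:
        if b.parent:
            kids_of.setdefault(b.parent, []).append(b)
    for kids in kids_of.values():
        for i, a in enumerate(kids):
            for c in kids[i + 1 :]:
                s = min(a.length_mm, c.length_mm)
                sep = float(np.linalg.norm(a.unit_direction() - c.unit_direction())) * s
                if sep < a.radius_mm + c.radius_mm + 1.0:
                    raise PhantomSpecError(
                        f"sibling branches {a.name}/{c.name} do not separate "
                        f"({sep:.1f} mm apart at {s:.0f} mm)"
                    )

    _check_overlap(spec, segs)


def _check_overlap(spec: PhantomSpec, segs, samples_per_mm: float = 1.0) -> None:
    """Non-adjacent branch tubes must not touch beyond shared junctions."""
    names = [b.name for b in spec.branches]
    adj = set()
    for b in spec.branches:
        if b.parent:
            adj.add(frozenset((b.name, b.parent)))
    sibs: dict[str, list[str]] = {}
    for b in spec.branches:
        if b.parent:
            sibs.setdefault(b.parent, []).append(b.name)
    for kids in sibs.values():
        for i, a in enumerate(kids):
            for c in kids[i + 1 :]:
                adj.add(frozenset((a, c)))

    sampled = {}
    for n in names:
        s, e = segs[n]
        k = max(2, int(np.linalg.norm(e - s) * samples_per_mm))
        t = np.linspace(0, 1, k)
        sampled[n] = s + t[:, None] * (e - s)
    for i, a in enumerate(names):
        ra = spec.branch(a).radius_mm
        for b in names[i + 1 :]:
            if frozenset((a, b)) in adj:
                continue
            rb = spec.branch(b).radius_mm
            d = np.linalg.norm(sampled[a][:, None, :] - sampled[b][None, :, :], axis=2)
            # tubes legitimately merge near junction complexes: ignore sample
            # pairs where either point sits close to any bifurcation node
            margin = ra + rb + 2.0
            junctions = np.array([segs[n][0] for n in names])
            da = np.linalg.norm(sampled[a][:, None, :] - junctions[None], axis=2).min(axis=1)
            db = np.linalg.norm(sampled[b][:, None, :] - junctions[None], axis=2).min(axis=1)
            near = (da[:, None] < margin) | (db[None, :] < margin)
            d = np.where(near, np.inf, d)
            if d.min() < ra + rb:
                raise PhantomSpecError(
                    f"branches {a} and {b} overlap beyond their shared bifurcation"
                )


# ---------------------------------------------------------------------------
# voxelization


def generate_phantom(spec: PhantomSpec) -> tuple[BinaryVolume, GroundTruth]:
    """Voxelize the spec into a binary mask plus per-voxel ground truth."""
    check_spec(spec)
    segs = build_segments(spec)
    gen = generations(spec)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    data = np.zeros(shape, dtype=bool)
    branch_id = np.full(shape, -1, dtype=np.int16)
    best = np.full(shape, np.inf, dtype=np.float32)

    for bid, b in enumerate(spec.branches):
        s, e = segs[b.name]
        lo = np.maximum(np.floor((np.minimum(s, e) - b.radius_mm) / spacing - 1), 0).astype(int)
        hi = np.minimum(
            np.ceil((np.maximum(s, e) + b.radius_mm) / spacing + 1), np.asarray(shape) - 1
        ).astype(int)
        ix, iy, iz = np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        )
        pts = np.stack([ix, iy, iz], axis=-1) * spacing
        v = e - s
        vv = float(v @ v)
        t = np.clip(((pts - s) @ v) / vv, 0.0, 1.0)
        d = np.linalg.norm(pts - (s + t[..., None] * v), axis=-1)
        inside = d <= b.radius_mm
        score = (d / b.radius_mm).astype(np.float32)
        sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        better = inside & (score < best[sl])
        data[sl] |= inside
        best[sl] = np.where(better, score, best[sl])
        sub = branch_id[sl]
        sub[better] = bid
        branch_id[sl] = sub

    if spec.trachea_gap_mm is not None:
        z0, z1 = spec.trachea_gap_mm
        zi = np.arange(shape[2]) * spacing[2]
        band = (zi >= z0) & (zi <= z1)
        tr = next(i for i, b in enumerate(spec.branches) if b.parent is None)
        cut = (branch_id == tr) & band[None, None, :]
        data[cut] = False
        branch_id[cut] = -1

    if spec.noise_amplitude_voxels > 0:
        data, branch_id = _add_surface_noise(data, branch_id, spec)

    rows = []
    for bid, b in enumerate(spec.branches):
        s, e = segs[b.name]
        rows.append(
            {
                "branch": b.name,
                "parent": b.parent or "",
                "lobe": b.lobe.name,
                "generation": gen[b.name],
                "radius_mm": b.radius_mm,
                "start_x": s[0], "start_y": s[1], "start_z": s[2],
                "end_x": e[0], "end_y": e[1], "end_z": e[2],
            }
        )
    table = pd.DataFrame(rows)
    volume = BinaryVolume(data, spacing, np.zeros(3))
    return volume, GroundTruth(branch_id=branch_id, table=table, spec=spec)


def _add_surface_noise(data, branch_id, spec):
    """Add <=1-voxel bumps at a random fraction of the boundary voxels."""
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed + 7919)
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(int(spec.noise_amplitude_voxels)):
        interior = ndimage.binary_erosion(data, structure=struct, border_value=0)
        bnd = np.argwhere(data & ~interior)
        n_pick = int(len(bnd) * spec.noise_fraction)
        if n_pick == 0:
            break
        pick = bnd[rng.choice(len(bnd), size=n_pick, replace=False)]
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        bumps = pick + offsets[rng.integers(6, size=n_pick)]
        ok = np.all((bumps >= 0) & (bumps < np.array(data.shape)), axis=1)
        bumps, src = bumps[ok], pick[ok]
        newly = ~data[bumps[:, 0], bumps[:, 1], bumps[:, 2]]
        bumps, src = bumps[newly], src[newly]
        data[bumps[:, 0], bumps[:, 1], bumps[:, 2]] = True
        branch_id[bumps[:, 0], bumps[:, 1], bumps[:, 2]] = branch_id[
            src[:, 0], src[:, 1], src[:, 2]
        ]
    return data, branch_id


# ---------------------------------------------------------------------------
# randomization


def randomize_spec(
    base: PhantomSpec,
    seed: int,
    angle_deg: float = 15.0,
    length_frac: float = 0.2,
    radius_frac: float = 0.2,
    max_retries: int = 50,
) -> PhantomSpec:
    """Jitter branch angles/lengths/radii while preserving the invariants.

    The trachea is kept fixed (it anchors the grid placement).  Jittered
    candidates violating :func:`check_spec` are resampled up to
    `max_retries` times.  All-zero jitter returns the base unchanged.
    """
    if angle_deg == 0 and length_frac == 0 and radius_frac == 0:
        return base
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        branches = []
        for b in base.branches:
            if b.parent is None:
                branches.append(dataclasses.replace(b))
                continue
            u = b.unit_direction()
            u2 = _jitter_direction(u, rng, angle_deg)
            length = b.length_mm * (1 + rng.uniform(-length_frac, length_frac))
            radius = b.radius_mm * (1 + rng.uniform(-radius_frac, radius_frac))
            branches.append(
                dataclasses.replace(
                    b, direction=tuple(u2), length_mm=float(length), radius_mm=float(radius)
                )
            )
        cand = dataclasses.replace(base, branches=branches, seed=int(seed))
        try:
            check_spec(cand)
            return cand
        except PhantomSpecError:
            continue
    raise PhantomSpecError(
        f"could not draw a valid jittered spec in {max_retries} attempts (seed={seed})"
    )


def _jitter_direction(u: np.ndarray, rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    """Rotate a unit vector by a random angle <= angle_deg about a random axis."""
    theta = np.deg2rad(rng.uniform(0, angle_deg))
    axis = rng.normal(size=3)
    axis -= axis @ u * u  # orthogonal component so the rotation tilts u
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return u
    axis /= n
    return u * np.cos(theta) + np.cross(axis, u) * np.sin(theta)
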