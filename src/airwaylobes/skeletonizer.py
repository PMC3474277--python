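"""Skeleton extraction from the repulsive force field.

The repulsive forces of the boundary charges cancel on the medial axis of a
tube and point toward it everywhere else, so the skeleton is found by
force-following: a streamline is seeded at every object voxel center and
advected along the (trilinearly interpolated) field direction with a fixed
step until it settles into the characteristic oscillation across the axis.
The terminal positions are quantized to the voxel grid, keeping one skeleton
point (the mean terminal position) per occupied voxel.

The advection direction is the *normalized* interpolated force: far from the
axis the radial component dominates and the point moves straight inward; on
the axis consecutive steps reverse and the two-step displacement collapses,
which is the convergence signal.  Step length defaults to half the smallest
voxel spacing so the oscillation amplitude stays well below one voxel.

Boundary voxels need care: they are themselves charges, and on a convex wall
the adjacent surface charges sit slightly *inside* the tangent plane, so the
exact force at the wall points outward — in tubes only two or three voxels
wide (where every voxel touches the wall) this would blow most streamlines
straight out of the object.  The advection field therefore excludes each
voxel's own surface patch: contributions of charges closer than about one
voxel diagonal are subtracted before tracing.  The stored force field is
untouched; this regularization applies to the advected copy only.  Boundary
seeds are additionally nudged one voxel toward the local object mass, and
streamlines that still exit the object are clamped and their terminals
discarded (they are not sinks), unless that would empty the skeleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError
from .force_field import ForceField
from .volume_io import BinaryVolume

log = logging.getLogger(__name__)

DEFAULT_MAX_STEPS = 1000
#: Two-step displacement below this fraction of the step length = converged.
CONVERGENCE_FRACTION = 0.5
#: Inward seed nudge for boundary voxels, in multiples of the min spacing.
BOUNDARY_NUDGE = 1.0
#: Near-field exclusion radius for the advection grid, in min-spacing units
#: (1.9 covers a voxel's full 26-neighborhood on an isotropic grid).
NEAR_FIELD_EXCLUSION = 1.9

# _advect terminal status codes
_CONVERGED, _DEAD, _EXITED, _MAXSTEPS = 0, 1, 2, 3


@dataclass
class SkeletonPointSet:
    """Ordered set of skeleton points S = {S_i} in physical coordinates.

    One point per occupied skeleton voxel; `positions` are sub-voxel mean
    terminal positions (mm), `voxel_indices` their containing voxels.
    """

    positions: np.ndarray  # (N_S, 3) mm
    voxel_indices: np.ndarray  # (N_S, 3) int
    source_volume: BinaryVolume

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def to_mask(self) -> np.ndarray:
        """Binary skeleton volume on the source grid."""
        mask = np.zeros(self.source_volume.shape, dtype=bool)
        i = self.voxel_indices
        mask[i[:, 0], i[:, 1], i[:, 2]] = True
        return mask

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.positions,
            delimiter=",",
            header="x_mm,y_mm,z_mm",
            comments="",
            fmt="%.4f",
        )


def _trilinear(grid: np.ndarray, idx_pos: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (nx,ny,nz,3) grid at float index coords."""
    shape = np.array(grid.shape[:3])
    g = np.clip(idx_pos, 0.0, shape - 1.000001)
    i0 = np.floor(g).astype(int)
    i0 = np.minimum(i0, shape - 2)
    f = g - i0
    out = np.zeros((len(g), 3))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                w = (wx * wy * wz)[:, None]
                out += w * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def _advect(
    starts: np.ndarray,
    grid: np.ndarray,
    volume: BinaryVolume,
    step: float,
    max_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Advect points along the normalized field.

    Returns (terminal positions, status codes) with statuses
    converged / dead (zero field) / exited (clamped at surface) / maxsteps.
    """
    p = np.asarray(starts, dtype=float).copy()
    n = len(p)
    prev = p.copy()  # position two steps back
    have_prev = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    terminals = p.copy()
    status = np.full(n, _MAXSTEPS, dtype=np.int8)

    for _ in range(max_steps):
        ai = np.where(active)[0]
        if len(ai) == 0:
            break
        idx_pos = (p[ai] - volume.origin) / volume.spacing
        F = _trilinear(grid, idx_pos)
        mag = np.linalg.norm(F, axis=1)
        # zero field: equilibrium point, stop where we are
        dead = mag < 1e-300
        if dead.any():
            di = ai[dead]
            terminals[di] = p[di]
            active[di] = False
            status[di] = _DEAD
            ai = ai[~dead]
            F, mag = F[~dead], mag[~dead]
            if len(ai) == 0:
                continue
        new_p = p[ai] + step * F / mag[:, None]
        # clamp trajectories leaving the object to the last interior position
        vox = volume.mm_to_indices(new_p)
        inb = volume.contains_index(vox)
        inside = inb.copy()
        if inb.any():
            v = vox[inb]
            inside[inb] = volume.data[v[:, 0], v[:, 1], v[:, 2]]
        exited = ~inside
        if exited.any():
            ei = ai[exited]
            terminals[ei] = p[ei]
            active[ei] = False
            status[ei] = _EXITED
        mi = ai[inside]
        if len(mi) == 0:
            continue
        new_in = new_p[inside]
        conv = have_prev[mi] & (
            np.linalg.norm(new_in - prev[mi], axis=1) < CONVERGENCE_FRACTION * step
        )
        # converged: the axis lies midway between the oscillating endpoints
        ci = mi[conv]
        terminals[ci] = 0.5 * (new_in[conv] + p[ci])
        active[ci] = False
        status[ci] = _CONVERGED
        prev[mi] = p[mi]
        have_prev[mi] = True
        p[mi] = new_in
    still = active.sum()
    if still:
        terminals[active] = p[active]
        log.debug("advection: %d streamline(s) hit max_steps", still)
    n_exited = int((status == _EXITED).sum())
    if n_exited:
        log.debug("advection: %d streamline(s) clamped at the object surface", n_exited)
    return terminals, status


def _advection_grid(field: ForceField, volume: BinaryVolume) -> np.ndarray:
    """Dense field for tracing, with each wall voxel's own patch removed.

    Subtracts from every *boundary* voxel's vector the contributions of
    charges within ``NEAR_FIELD_EXCLUSION * min(spacing)`` of it, so a wall
    voxel does not feel the wall segment it belongs to (whose net push is
    outward on convex walls).  Interior voxels keep the exact sum.
    """
    from scipy.spatial import cKDTree

    grid = field.as_grid()
    r_excl = NEAR_FIELD_EXCLUSION * float(volume.spacing.min())
    charge_vox = volume.mm_to_indices(field.charges)
    pts = field.charges  # regularize at the boundary voxels only
    tree = cKDTree(field.charges)
    pairs = tree.query_ball_point(pts, r=r_excl)
    counts = np.fromiter((len(p) for p in pairs), dtype=np.intp)
    if counts.sum() == 0:
        return grid
    flat = np.concatenate([np.asarray(p, dtype=np.intp) for p in pairs if p])
    rep = np.repeat(np.arange(len(pts)), counts)
    d = pts[rep] - field.charges[flat]
    R = np.linalg.norm(d, axis=1)
    ok = R > 1e-12
    w = np.zeros_like(R)
    w[ok] = R[ok] ** (-(field.order + 1.0))
    contrib = d * w[:, None]
    sub = np.zeros((len(pts), 3))
    for c in range(3):
        sub[:, c] = np.bincount(rep, weights=contrib[:, c], minlength=len(pts))
    grid[charge_vox[:, 0], charge_vox[:, 1], charge_vox[:, 2]] -= sub
    return grid


def _inward_nudged_seeds(volume: BinaryVolume) -> np.ndarray:
    """Object voxel centers, with boundary voxels nudged toward local mass."""
    from scipy import ndimage

    idx = volume.object_indices()
    seeds = volume.indices_to_mm(idx)
    fm = volume.data.astype(float)
    normal = np.zeros(volume.shape + (3,))
    for a in range(3):
        k = np.fromfunction(lambda i, j, l: [i - 1, j - 1, l - 1][a], (3, 3, 3))
        normal[..., a] = ndimage.correlate(fm, k, mode="constant")
    nv = normal[idx[:, 0], idx[:, 1], idx[:, 2]]
    mag = np.linalg.norm(nv, axis=1)
    interior = ndimage.binary_erosion(
        volume.data, ndimage.generate_binary_structure(3, 1), border_value=0
    )
    on_boundary = ~interior[idx[:, 0], idx[:, 1], idx[:, 2]]
    move = on_boundary & (mag > 1e-9)
    seeds = seeds.astype(float)
    seeds[move] += BOUNDARY_NUDGE * float(volume.spacing.min()) * nv[move] / mag[move, None]
    return seeds


def trace_streamline(
    start: np.ndarray,
    field: ForceField,
    step: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> np.ndarray:
    """Trace a single streamline from `start` (mm); returns its terminal."""
    volume = field.volume
    if step is None:
        step = 0.5 * float(volume.spacing.min())
    if max_steps <= 0:
        return np.asarray(start, dtype=float)
    grid = field.as_grid()
    terminals, _ = _advect(np.atleast_2d(start), grid, volume, step, max_steps)
    return terminals[0]


def extract_skeleton(
    field: ForceField,
    volume: BinaryVolume | None = None,
    step: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> SkeletonPointSet:
    """Extract the skeleton point set of the object.

    Seeds one streamline per object voxel center, advects all of them to
    convergence in a single vectorized batch, then thins the terminals to one
    representative point per occupied voxel.
    """
    volume = volume or field.volume
    if volume.n_object == 0:
        raise EmptyMaskError("cannot skeletonize an empty object")
    if step is None:
        step = 0.5 * float(volume.spacing.min())
    all_seeds = volume.indices_to_mm(volume.object_indices())
    seeds = _inward_nudged_seeds(volume)
    grid = _advection_grid(field, volume)
    terminals, status = _advect(seeds, grid, volume, step, max_steps)

    # exit-clamped trajectories never reached a sink; drop them unless the
    # object is so small that nothing else remains
    keep = status != _EXITED
    if keep.any():
        terminals, seeds = terminals[keep], all_seeds[keep]
    else:
        log.warning("extract_skeleton: all streamlines exited; keeping clamped terminals")
        seeds = all_seeds

    vox = volume.mm_to_indices(terminals)
    # guard: a midpoint may quantize just outside the object; snap to the seed voxel
    v = np.clip(vox, 0, np.array(volume.shape) - 1)
    on_obj = volume.data[v[:, 0], v[:, 1], v[:, 2]]
    if not on_obj.all():
        bad = ~on_obj
        vox[bad] = volume.mm_to_indices(seeds[bad])
        terminals[bad] = seeds[bad]
    # one skeleton point per occupied voxel: mean of its terminals
    keys = (
        vox[:, 0].astype(np.int64) * volume.shape[1] * volume.shape[2]
        + vox[:, 1].astype(np.int64) * volume.shape[2]
        + vox[:, 2].astype(np.int64)
    )
    order = np.argsort(keys, kind="stable")
    keys_s, term_s, vox_s = keys[order], terminals[order], vox[order]
    uniq, starts_i, counts = np.unique(keys_s, return_index=True, return_counts=True)
    positions = np.add.reduceat(term_s, starts_i, axis=0) / counts[:, None]
    voxels = vox_s[starts_i]
    log.info("skeleton: %d points from %d seeds", len(positions), len(seeds))
    return SkeletonPointSet(positions=positions, voxel_indices=voxels, source_volume=volume)
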