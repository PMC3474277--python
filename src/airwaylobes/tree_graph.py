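"""Undirected acyclic graph over skeleton points and its branch decomposition.

The skeleton point set is organized into a spanning tree by iterating two
moves: (Step 1) connect the globally nearest pair between a visited vertex
with fewer than three neighbors and an unvisited point, then (Step 2)
greedily chain the last-inserted point to its nearest unvisited neighbor as
long as that distance stays below the merge distance (default 2 mm); the
loop repeats until every point is inserted.  The degree cap of three means
every vertex is a terminate point (degree 1), a run point (degree 2) or a
bifurcation point (degree 3); anatomical trifurcations appear as two nearby
bifurcations.

Cutting the tree at its bifurcation points yields the individual airway
branches.  The trachea is the branch with the largest lumen volume, and
rooting the branch adjacency at the trachea gives parent/child relations
and generations (trachea = generation 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .labels import LobeLabel
from .skeletonizer import SkeletonPointSet

log = logging.getLogger(__name__)

DEFAULT_MERGE_MM = 2.0
DEFAULT_PRUNE_MM = 3.0
#: Step-1 joins longer than this are logged: they usually flag segmentation gaps.
LONG_JOIN_WARN_MM = 10.0


def build_uag(
    points: SkeletonPointSet | np.ndarray,
    merge_mm: float = DEFAULT_MERGE_MM,
    seed: int | None = 0,
    start_index: int | None = None,
) -> nx.Graph:
    """Build the undirected acyclic graph over the skeleton points.

    Nodes are point indices with a ``pos`` attribute (mm).  The graph records
    its insertion history in ``G.graph["insertion_rounds"]``: one list of
    inserted indices per outer round (each round ends when the greedy chain
    breaks).  The start vertex is drawn from ``seed`` unless ``start_index``
    is given explicitly.
    """
    P = points.positions if isinstance(points, SkeletonPointSet) else np.asarray(points, float)
    n = len(P)
    if n == 0:
        raise ValueError("cannot build a graph over zero skeleton points")
    if start_index is None:
        start_index = int(np.random.default_rng(seed).integers(n)) if seed is not None else 0

    g = nx.Graph()
    for i in range(n):
        g.add_node(i, pos=P[i])
    g.graph["start_index"] = start_index
    rounds: list[list[int]] = []
    g.graph["insertion_rounds"] = rounds
    if n == 1:
        return g

    visited = np.zeros(n, dtype=bool)
    visited[start_index] = True
    degree = np.zeros(n, dtype=int)

    def nearest_unvisited(j: int) -> tuple[int, float]:
        d = np.linalg.norm(P - P[j], axis=1)
        d[visited] = np.inf
        k = int(np.argmin(d))  # ties -> lowest index
        return k, float(d[k])

    while not visited.all():
        # Step 1: nearest (visited & degree<3, unvisited) pair
        eligible = np.where(visited & (degree < 3))[0]
        unvisited = np.where(~visited)[0]
        tree = cKDTree(P[unvisited])
        dists, nn = tree.query(P[eligible], k=1)
        a = int(np.argmin(dists))  # ties -> lowest eligible index
        i, j = int(eligible[a]), int(unvisited[int(nn[a])])
        if dists[a] > LONG_JOIN_WARN_MM:
            log.warning(
                "build_uag: long join of %.1f mm between fragments (possible "
                "segmentation gap)",
                dists[a],
            )
        g.add_edge(i, j, length=float(dists[a]))
        visited[j] = True
        degree[i] += 1
        degree[j] += 1
        this_round = [j]
        # Step 2: greedy chain from the last-inserted point
        last = j
        while True:
            if visited.all():
                break
            k, dk = nearest_unvisited(last)
            if dk >= merge_mm:
                break
            g.add_edge(last, k, length=dk)
            visited[k] = True
            degree[last] += 1
            degree[k] += 1
            this_round.append(k)
            last = k
        rounds.append(this_round)
    return g


@dataclass
class Branch:
    """A maximal skeleton path between terminate/bifurcation points."""

    id: int
    nodes: list[int]  # ordered vertex path through the UAG
    length_mm: float  # sum of consecutive point distances
    lumen_volume_mm3: float | None = None
    label: LobeLabel = LobeLabel.UNLABELED

    @property
    def endpoints(self) -> tuple[int, int]:
        return self.nodes[0], self.nodes[-1]


def _path_length(g: nx.Graph, nodes: list[int]) -> float:
    pos = np.array([g.nodes[n]["pos"] for n in nodes])
    if len(pos) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def decompose_branches(g: nx.Graph) -> list[Branch]:
    """Cut the UAG at its bifurcation points into individual branches.

    Every edge belongs to exactly one branch; branch endpoints have degree
    1 or 3 in the graph.  A pure path graph is a single branch; an isolated
    vertex is a degenerate single-node branch.
    """
    if g.number_of_nodes() == 0:
        return []
    if g.number_of_edges() == 0:
        return [Branch(id=0, nodes=[next(iter(g.nodes))], length_mm=0.0)]
    junctions = [v for v in g.nodes if g.degree(v) != 2]
    branches: list[Branch] = []
    seen_edges: set[frozenset] = set()
    for j in sorted(junctions):
        for nbr in sorted(g[j]):
            e = frozenset((j, nbr))
            if e in seen_edges:
                continue
            path = [j, nbr]
            seen_edges.add(e)
            while g.degree(path[-1]) == 2:
                a, b = g[path[-1]]
                nxt = b if a == path[-2] else a
                seen_edges.add(frozenset((path[-1], nxt)))
                path.append(nxt)
            branches.append(Branch(id=len(branches), nodes=path, length_mm=_path_length(g, path)))
    return branches


def prune_short_terminal_branches(
    g: nx.Graph, min_length_mm: float = DEFAULT_PRUNE_MM
) -> nx.Graph:
    """Remove short terminal spurs hanging off bifurcation points.

    Streamline terminals that stop early leave 1–2-point spurs which would
    forge spurious bifurcations; repeatedly delete terminal branches shorter
    than `min_length_mm` whose junction endpoint is a bifurcation, keeping
    the junction itself.  Returns a pruned copy of the graph.
    """
    g = g.copy()
    while True:
        branches = decompose_branches(g)
        if len(branches) <= 1:
            return g
        candidates = []
        for b in branches:
            u, v = b.endpoints
            du, dv = g.degree(u), g.degree(v)
            if b.length_mm >= min_length_mm:
                continue
            # orient so the junction is kept and the dangling tip removed
            if du >= 3 and dv == 1:
                candidates.append((b.length_mm, b.nodes[1:]))
            elif dv >= 3 and du == 1:
                candidates.append((b.length_mm, b.nodes[:-1]))
        if not candidates:
            return g
        # shortest spur first; degrees are re-evaluated after each removal
        candidates.sort(key=lambda c: c[0])
        g.remove_nodes_from(candidates[0][1])


def find_trachea(branches: list[Branch], g: nx.Graph | None = None) -> Branch:
    """The branch with the largest lumen volume (ties: most superior endpoint).

    Requires lumen volumes filled in by the voxel-assignment stage.
    """
    if not branches:
        raise ValueError("no branches to search")
    vols = [b.lumen_volume_mm3 for b in branches]
    if any(v is None for v in vols):
        raise ValueError("lumen volumes must be computed before find_trachea")
    vmax = max(vols)
    best = [b for b in branches if b.lumen_volume_mm3 == vmax]
    if len(best) > 1 and g is not None:
        log.warning("find_trachea: %d branches tie on lumen volume; picking most superior", len(best))
        best.sort(
            key=lambda b: -max(g.nodes[b.nodes[0]]["pos"][2], g.nodes[b.nodes[-1]]["pos"][2])
        )
    return best[0]


class BranchTree:
    """Branches rooted at the trachea, with parent/child links and generations."""

    def __init__(self, g: nx.Graph, branches: list[Branch], trachea: Branch):
        self.graph = g
        self.branches = {b.id: b for b in branches}
        self.root_id = trachea.id
        self.parent: dict[int, int | None] = {}
        self.children: dict[int, list[int]] = {b.id: [] for b in branches}
        self.generation: dict[int, int] = {}
        self.distal_node: dict[int, int] = {}
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        by_endpoint: dict[int, list[int]] = {}
        for b in self.branches.values():
            for e in set(b.endpoints):
                by_endpoint.setdefault(e, []).append(b.id)
        root = self.branches[self.root_id]
        u, v = root.endpoints
        # the trachea's proximal end is its free (degree-1) endpoint; if both
        # or neither are free, the more superior one (larger z) is proximal
        du, dv = self.graph.degree(u), self.graph.degree(v)
        if du == 1 and dv != 1:
            proximal = u
        elif dv == 1 and du != 1:
            proximal = v
        else:
            zu = self.graph.nodes[u]["pos"][2]
            zv = self.graph.nodes[v]["pos"][2]
            proximal = u if zu >= zv else v
        self.parent[self.root_id] = None
        self.generation[self.root_id] = 0
        self.distal_node[self.root_id] = v if proximal == u else u

        queue = [self.root_id]
        placed = {self.root_id}
        while queue:
            bid = queue.pop(0)
            dnode = self.distal_node[bid]
            for cid in sorted(by_endpoint.get(dnode, [])):
                if cid in placed:
                    continue
                placed.add(cid)
                self.parent[cid] = bid
                self.children[bid].append(cid)
                self.generation[cid] = self.generation[bid] + 1
                cu, cv = self.branches[cid].endpoints
                self.distal_node[cid] = cv if cu == dnode else cu
                queue.append(cid)
        orphans = set(self.branches) - placed
        if orphans:
            log.warning("build_branch_tree: %d branch(es) unreachable from trachea", len(orphans))
            for bid in sorted(orphans):
                self.parent[bid] = None
                self.generation[bid] = 0
                u, v = self.branches[bid].endpoints
                self.distal_node[bid] = v

    # -- queries -----------------------------------------------------------
    def node_pos(self, node: int) -> np.ndarray:
        return np.asarray(self.graph.nodes[node]["pos"], dtype=float)

    def distal_pos(self, bid: int) -> np.ndarray:
        """Position (mm) of a branch's distal endpoint."""
        return self.node_pos(self.distal_node[bid])

    def proximal_node(self, bid: int) -> int:
        u, v = self.branches[bid].endpoints
        return u if self.distal_node[bid] == v else v

    def subtree_ids(self, bid: int) -> list[int]:
        """Branch ids of the subtree rooted at `bid` (inclusive, BFS order)."""
        out, queue = [], [bid]
        while queue:
            b = queue.pop(0)
            out.append(b)
            queue.extend(self.children[b])
        return out

    def terminal_branches(self, within: list[int] | None = None) -> list[int]:
        ids = within if within is not None else list(self.branches)
        return [b for b in ids if not self.children[b]]

    def first_generation(self) -> list[int]:
        return list(self.children[self.root_id])

    def branch_ids(self) -> list[int]:
        return sorted(self.branches)


def build_branch_tree(g: nx.Graph, branches: list[Branch], trachea: Branch) -> BranchTree:
    """Root the branch adjacency at the trachea and assign generations."""
    return BranchTree(g, branches, trachea)


def total_length(branches: list[Branch]) -> float:
    return float(sum(b.length_mm for b in branches))
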