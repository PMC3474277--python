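"""Graph construction, branch decomposition and the rooted branch tree.

Includes the nine-point worked example whose insertion order and branch
decomposition are known exactly.
"""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaylobes import tree_graph
from airwaylobes.tree_graph import (
    Branch,
    build_branch_tree,
    build_uag,
    decompose_branches,
    find_trachea,
    prune_short_terminal_branches,
)

# a/b/c on a line, two arms d-e and f-g-h fanning out from c, i beyond a
NINE_POINTS = {
    "a": (0.0, 0.0, 0.0),
    "b": (1.2, 0.0, 0.0),
    "c": (2.4, 0.0, 0.0),
    "d": (3.4, 0.8, 0.0),
    "e": (4.4, 1.6, 0.0),
    "f": (3.4, -0.8, 0.0),
    "g": (4.4, -1.6, 0.0),
    "h": (5.4, -2.4, 0.0),
    "i": (-2.2, 0.0, 0.0),
}


class TestNinePointExample:
    @pytest.fixture(scope="class")
    def graph(self):
        names = list(NINE_POINTS)
        P = np.array([NINE_POINTS[n] for n in names])
        g = build_uag(P, merge_mm=2.0, start_index=names.index("a"))
        return names, g

    def test_insertion_sequence(self, graph):
        names, g = graph
        rounds = [
            "".join(names[i] for i in r) for r in g.graph["insertion_rounds"]
        ]
        assert rounds == ["bcde", "fgh", "i"]

    def test_branch_decomposition(self, graph):
        names, g = graph
        paths = {
            "".join(names[n] for n in b.nodes) for b in decompose_branches(g)
        }
        canon = {min(p, p[::-1]) for p in paths}
        assert canon == {"cde", "cfgh", "cbai"}


def random_cloud(seed, n=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 60))
    return rng.uniform(0, 30, size=(n, 3))


class TestGraphInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_spanning_tree_properties(self, seed):
        P = random_cloud(seed)
        g = build_uag(P, merge_mm=2.0, seed=seed)
        assert g.number_of_nodes() == len(P)
        assert g.number_of_edges() == len(P) - 1
        assert max(dict(g.degree).values()) <= 3
        assert nx.is_tree(g)

    def test_three_collinear_points_form_a_path(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        g = build_uag(P, start_index=0)
        assert sorted(dict(g.degree).values()) == [1, 1, 2]
        assert len(decompose_branches(g)) == 1

    def test_start_point_invariance_on_well_separated_phantom(self):
        """Branch structure is independent of the random start vertex."""
        # Y-shaped cloud: three arms of 10 points each, 1 mm apart
        arms = []
        for d in ([1, 0, 0], [-0.7, 0.7, 0], [-0.7, -0.7, 0]):
            t = np.arange(1, 11)[:, None]
            arms.append(t * np.asarray(d, dtype=float))
        P = np.vstack([[0, 0, 0]] + arms)
        signatures = set()
        for seed in range(10):
            g = build_uag(P, merge_mm=2.0, seed=seed)
            lens = tuple(sorted(len(b.nodes) for b in decompose_branches(g)))
            signatures.add(lens)
        assert len(signatures) == 1

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_decomposition_partitions_edges(self, seed):
        P = random_cloud(seed)
        g = build_uag(P, merge_mm=2.0, seed=0)
        branches = decompose_branches(g)
        covered = [
            frozenset(e) for b in branches for e in zip(b.nodes, b.nodes[1:])
        ]
        assert len(covered) == g.number_of_edges()
        assert set(covered) == {frozenset(e) for e in g.edges}

    def test_branch_count_follows_bifurcation_count(self):
        """A binary tree with k degree-3 vertices splits into 2k+1 branches."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = nx.Graph()
            g.add_node(0, pos=np.zeros(3))
            leaves = [0]
            next_id = 1
            # grow a random binary tree with spaced-out chain vertices
            for _ in range(rng.integers(1, 6)):
                leaf = leaves.pop(rng.integers(len(leaves)))
                for _ in range(2):
                    chain = rng.integers(1, 4)
                    prev = leaf
                    for _ in range(chain):
                        g.add_node(next_id, pos=rng.uniform(0, 50, 3))
                        g.add_edge(prev, next_id)
                        prev = next_id
                        next_id += 1
                    leaves.append(prev)
            k = sum(1 for v in g.nodes if g.degree(v) == 3)
            assert len(decompose_branches(g)) == 2 * k + 1

    def test_total_length_is_conserved(self):
        P = random_cloud(3, n=40)
        g = build_uag(P, merge_mm=2.0, seed=1)
        total = sum(
            np.linalg.norm(g.nodes[u]["pos"] - g.nodes[v]["pos"]) for u, v in g.edges
        )
        branches = decompose_branches(g)
        assert np.isclose(sum(b.length_mm for b in branches), total)


class TestPruning:
    def test_short_spur_removed_and_junction_merged(self):
        g = nx.Graph()
        pts = {i: np.array([float(i), 0, 0]) for i in range(8)}
        pts[10] = np.array([3.0, 0.8, 0])  # 0.8 mm spur off vertex 3
        for i, p in pts.items():
            g.add_node(i, pos=p)
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (3, 10)]:
            g.add_edge(a, b)
        pruned = prune_short_terminal_branches(g, min_length_mm=3.0)
        assert not pruned.has_node(10)
        assert len(decompose_branches(pruned)) == 1

    def test_long_terminal_branches_survive(self):
        g = nx.Graph()
        coords = [(0, 0), (4, 0), (8, 0), (4, 4), (4, 8)]
        for i, (x, y) in enumerate(coords):
            g.add_node(i, pos=np.array([float(x), float(y), 0]))
        for a, b in [(0, 1), (1, 2), (1, 3), (3, 4)]:
            g.add_edge(a, b)
        pruned = prune_short_terminal_branches(g, min_length_mm=3.0)
        assert pruned.number_of_nodes() == 5


class TestTracheaAndBranchTree:
    def _chain(self, g, start_pos, direction, n, first_id):
        ids = []
        prev = None
        for t in range(n):
            nid = first_id + t
            g.add_node(nid, pos=np.asarray(start_pos) + t * np.asarray(direction))
            if prev is not None:
                g.add_edge(prev, nid)
            prev = nid
            ids.append(nid)
        return ids

    def test_largest_lumen_branch_wins(self):
        branches = [
            Branch(0, [0, 1], 5.0, lumen_volume_mm3=100.0),
            Branch(1, [1, 2], 5.0, lumen_volume_mm3=900.0),
            Branch(2, [1, 3], 5.0, lumen_volume_mm3=50.0),
        ]
        assert find_trachea(branches).id == 1

    def test_volume_tie_broken_by_superior_endpoint(self):
        g = nx.Graph()
        g.add_node(0, pos=np.array([0.0, 0, 0]))
        g.add_node(1, pos=np.array([0.0, 0, 10]))
        g.add_node(2, pos=np.array([5.0, 0, 0]))
        g.add_node(3, pos=np.array([5.0, 0, -10]))
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        branches = [
            Branch(0, [0, 1], 10.0, lumen_volume_mm3=100.0),
            Branch(1, [2, 3], 10.0, lumen_volume_mm3=100.0),
        ]
        assert find_trachea(branches, g).id == 0

    def test_missing_volumes_rejected(self):
        with pytest.raises(ValueError):
            find_trachea([Branch(0, [0, 1], 1.0)])

    def test_generations_increase_by_one(self):
        # trachea (superior, along -z) splitting into two arms
        g = nx.Graph()
        tr = self._chain(g, [0, 0, 30], [0, 0, -1], 10, 0)
        left = self._chain(g, [1, 0, 20], [1, 0, -1], 8, 100)
        right = self._chain(g, [-1, 0, 20], [-1, 0, -1], 8, 200)
        g.add_edge(tr[-1], left[0])
        g.add_edge(tr[-1], right[0])
        ll = self._chain(g, [9, 0, 11], [1, 0, -1], 5, 300)
        lr = self._chain(g, [7, -1, 11], [0, -1, -1], 5, 400)
        g.add_edge(left[-1], ll[0])
        g.add_edge(left[-1], lr[0])
        branches = decompose_branches(g)
        for i, b in enumerate(branches):
            b.lumen_volume_mm3 = 1000.0 if 0 in b.nodes else 10.0
        tree = build_branch_tree(g, branches, find_trachea(branches, g))
        assert tree.generation[tree.root_id] == 0
        for bid, parent in tree.parent.items():
            if parent is not None:
                assert tree.generation[bid] == tree.generation[parent] + 1
        assert len(tree.first_generation()) == 2
        # distal endpoints point away from the trachea
        root_distal = tree.distal_pos(tree.root_id)
        np.testing.assert_allclose(root_distal, [0, 0, 21])

    def test_single_branch_tree_has_depth_zero(self):
        g = nx.Graph()
        self._chain(g, [0, 0, 0], [0, 0, 1], 5, 0)
        branches = decompose_branches(g)
        branches[0].lumen_volume_mm3 = 1.0
        tree = build_branch_tree(g, branches, branches[0])
        assert tree.generation == {branches[0].id: 0}
        assert tree.children[branches[0].id] == []
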