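"""Anatomical labeling rules and the BC/AB self-correction on synthetic trees.

Trees are built directly from straight polyline segments (1 mm vertex
spacing) so every rule can be exercised with exact, known geometry, in the
LPS frame (x left, y posterior, z superior).
"""

import networkx as nx
import numpy as np
import pytest

from airwaylobes.errors import ClassificationError
from airwaylobes.labels import LobeLabel
from airwaylobes.lobe_classifier import classify, classify_lungs, self_correct
from airwaylobes.tree_graph import build_branch_tree, decompose_branches, find_trachea


def make_tree(segments, root_start=(50.0, 50.0, 40.0)):
    """Build a BranchTree from (name, parent, end_xyz) straight segments.

    Returns (tree, name_of_branch_id).  The root segment must be first and
    have parent None; children start at their parent's end point.
    """
    g = nx.Graph()
    next_id = [0]

    def add_node(pos):
        g.add_node(next_id[0], pos=np.asarray(pos, dtype=float))
        next_id[0] += 1
        return next_id[0] - 1

    span = {}
    root_node = add_node(root_start)
    starts = {None: (np.asarray(root_start, dtype=float), root_node)}
    for name, parent, end in segments:
        start, snode = starts[parent]
        end = np.asarray(end, dtype=float)
        n = max(2, int(np.ceil(np.linalg.norm(end - start))))
        prev = snode
        for t in np.linspace(0, 1, n + 1)[1:]:
            node = add_node(start + t * (end - start))
            g.add_edge(prev, node)
            prev = node
        span[name] = frozenset((snode, prev))
        starts[name] = (end, prev)

    branches = decompose_branches(g)
    names = {}
    for b in branches:
        for name, endpoints in span.items():
            if frozenset(b.endpoints) == endpoints:
                names[b.id] = name
        b.lumen_volume_mm3 = 10.0
    for b in branches:
        if root_node in b.nodes:
            b.lumen_volume_mm3 = 1000.0
    tree = build_branch_tree(g, branches, find_trachea(branches, g))
    return tree, names


NORMAL_SEGMENTS = [
    ("trachea", None, (50, 50, 30)),
    ("L_main", "trachea", (60, 50, 24)),
    ("LUL", "L_main", (66, 46, 32)),
    ("LLL", "L_main", (66, 56, 14)),
    ("R_main", "trachea", (42, 50, 24)),
    ("RUL", "R_main", (34, 46, 32)),
    ("intermedius", "R_main", (42, 50, 14)),
    ("RML", "intermedius", (36, 42, 20)),
    ("RLL", "intermedius", (46, 58, 4)),
]


def labels_by_name(tree, names, labels):
    return {names[b]: labels[b] for b in labels if b in names}


class TestNormalRules:
    @pytest.fixture(scope="class")
    def classified(self):
        tree, names = make_tree(NORMAL_SEGMENTS)
        result = classify(tree)
        return tree, names, result

    def test_expected_label_per_branch(self, classified):
        tree, names, result = classified
        got = labels_by_name(tree, names, result.labels)
        assert got == {
            "trachea": LobeLabel.TRACHEA,
            "L_main": LobeLabel.LLL,
            "LUL": LobeLabel.LUL,
            "LLL": LobeLabel.LLL,
            "R_main": LobeLabel.RLL,
            "RUL": LobeLabel.RUL,
            "intermedius": LobeLabel.RLL,
            "RML": LobeLabel.RML,
            "RLL": LobeLabel.RLL,
        }

    def test_every_branch_labeled(self, classified):
        tree, _, result = classified
        assert set(result.labels) == set(tree.branch_ids())
        assert LobeLabel.UNLABELED not in result.labels.values()

    def test_correction_not_fired_on_normal_topology(self, classified):
        _, _, result = classified
        assert not result.correction_fired

    def test_mirrored_tree_swaps_sides(self):
        mirrored = [
            (n, p, (100 - e[0], e[1], e[2])) for n, p, e in NORMAL_SEGMENTS
        ]
        tree, names = make_tree(mirrored)
        got = labels_by_name(tree, names, classify(tree).labels)
        # the anatomical left (large x) is now the former right subtree
        assert got["L_main"] in (LobeLabel.RLL, LobeLabel.RML)
        assert got["LUL"] == LobeLabel.RUL
        assert got["R_main"] == LobeLabel.LLL
        assert got["RUL"] == LobeLabel.LUL


class TestDegenerateTopologies:
    def test_single_first_generation_branch_is_an_error(self):
        tree, _ = make_tree(
            [("trachea", None, (50, 50, 30)), ("stump", "trachea", (50, 50, 20))]
        )
        with pytest.raises(ClassificationError):
            classify_lungs(tree)

    def test_left_main_single_child_descends_one_level(self):
        segs = [s for s in NORMAL_SEGMENTS if s[0] not in ("LUL", "LLL")] + [
            ("L_inter", "L_main", (64, 50, 20)),
            ("LUL", "L_inter", (68, 46, 30)),
            ("LLL", "L_inter", (70, 56, 10)),
        ]
        tree, names = make_tree(segs)
        got = labels_by_name(tree, names, classify(tree).labels)
        assert got["LUL"] == LobeLabel.LUL
        assert got["LLL"] == LobeLabel.LLL

    def test_leafless_left_main_left_unlabeled(self):
        segs = [s for s in NORMAL_SEGMENTS if s[0] not in ("LUL", "LLL")]
        tree, names = make_tree(segs)
        result = classify(tree)
        got = labels_by_name(tree, names, result.labels)
        assert got["L_main"] == LobeLabel.UNLABELED
        assert result.warnings

    def test_right_chain_without_bifurcation_is_all_rll_with_warning(self):
        segs = [s for s in NORMAL_SEGMENTS if s[0] not in ("RML", "RLL")]
        tree, names = make_tree(segs)
        result = classify(tree)
        got = labels_by_name(tree, names, result.labels)
        assert got["intermedius"] == LobeLabel.RLL
        assert any("RML" in w for w in result.warnings)

    def test_sibling_terminals_put_node_d_at_their_parent(self):
        tree, names = make_tree(NORMAL_SEGMENTS)
        result = classify(tree)
        inter_id = {v: k for k, v in names.items()}["intermedius"]
        d = np.asarray(result.landmarks["D"])
        np.testing.assert_allclose(d, tree.distal_pos(inter_id))


ABNORMAL_SEGMENTS = [
    ("trachea", None, (50, 50, 30)),
    ("L_main", "trachea", (60, 50, 24)),
    ("LUL", "L_main", (66, 46, 32)),
    ("LLL", "L_main", (66, 56, 14)),
    ("R_main", "trachea", (42, 50, 24)),  # AB = 10
    ("RUL1", "R_main", (34, 46, 32)),
    ("BC_seg", "R_main", (42, 50, 21)),  # BC = 3, ratio 0.3
    ("RUL2", "BC_seg", (36, 47, 28)),
    ("CD_seg", "BC_seg", (42, 50, 13)),
    ("RML", "CD_seg", (36, 42, 19)),
    ("RLL", "CD_seg", (46, 58, 3)),
]


class TestSelfCorrection:
    def test_short_bc_detected_and_rul_restored(self):
        tree, names = make_tree(ABNORMAL_SEGMENTS)
        uncorrected = classify(tree, apply_correction=False)
        got0 = labels_by_name(tree, names, uncorrected.labels)
        assert got0["RUL2"] != LobeLabel.RUL  # the initial rules miss it

        result = classify(tree, apply_correction=True)
        got = labels_by_name(tree, names, result.labels)
        assert result.correction_fired
        assert np.isclose(result.landmarks["AB_mm"], 10.0)
        assert np.isclose(result.landmarks["BC_mm"], 3.0)
        assert got["RUL1"] == LobeLabel.RUL
        assert got["RUL2"] == LobeLabel.RUL
        assert got["RML"] == LobeLabel.RML
        assert got["RLL"] == LobeLabel.RLL

    def test_ratio_at_threshold_does_not_fire(self):
        segs = [list(s) for s in ABNORMAL_SEGMENTS]
        segs[6][2] = (42, 50, 19)  # BC = 5 -> ratio exactly 0.5
        segs[8][2] = (42, 50, 11)
        tree, names = make_tree([tuple(s) for s in segs])
        result = classify(tree, apply_correction=True)
        assert np.isclose(result.landmarks["BC_over_AB"], 0.5)
        assert not result.correction_fired

    def test_no_correction_leaves_labels_bit_identical(self):
        tree, _ = make_tree(NORMAL_SEGMENTS)
        base = classify(tree, apply_correction=False).labels
        corrected = self_correct(tree, base, ratio_threshold=0.5)
        assert corrected == base

    def test_firing_never_shrinks_the_rul(self):
        tree, _ = make_tree(ABNORMAL_SEGMENTS)
        base = classify(tree, apply_correction=False).labels
        corrected = self_correct(tree, base, ratio_threshold=0.5)
        n_before = sum(1 for v in base.values() if v == LobeLabel.RUL)
        n_after = sum(1 for v in corrected.values() if v == LobeLabel.RUL)
        assert n_after >= n_before

    def test_missing_node_c_skips_correction(self):
        segs = ABNORMAL_SEGMENTS[:7]  # BC_seg is terminal: no node D
        tree, _ = make_tree(segs)
        base = classify(tree, apply_correction=False).labels
        corrected = self_correct(tree, base, ratio_threshold=0.5)
        assert corrected == base
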