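"""Anatomical classification of airway branches into lobes, with self-correction.

Rules operate in the canonical LPS frame (x → patient left, y → posterior,
z → superior) on the *distal* endpoints of branches:

* left vs right lung: the first-generation branch whose distal endpoint has
  the larger x is the left main bronchus;
* LUL vs LLL: the left-main child subtree with the larger distal z is the
  upper lobe;
* RUL: the right-main child subtree with the larger distal z;
* RML vs RLL: within the remaining right subtree (rooted at node C, the end
  of the bronchus intermedius), the terminal endpoint E maximizing (z − y)
  marks the middle lobe (anterior-superior on the sagittal view) and the
  terminal endpoint F minimizing (z − y) the lower lobe; their lowest common
  ancestor bifurcation D splits them — the D-child subtree containing E is
  RML, everything else under C is RLL.

Main bronchi and the bronchus intermedius carry the lower-lobe label of
their side, so every branch of a topologically normal tree ends up labeled.

Self-correction: let A be the carina, B the end of the right main bronchus
and C the next bifurcation along the right path.  In the normal topology
BC/AB is near or above one; when the upper-lobe branches split across two
closely spaced nodes, BC/AB falls well below one and the initial rules push
a true RUL branch into RML/RLL.  If BC/AB < 0.5 the subtrees branching off
at both B and C are relabeled RUL and the RML/RLL split is recomputed from
the next node D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError
from .labels import LobeLabel
from .tree_graph import BranchTree

log = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 0.5


@dataclass
class ClassificationResult:
    """Per-branch labels plus landmarks and diagnostics."""

    labels: dict[int, LobeLabel]
    landmarks: dict[str, object] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    correction_fired: bool = False


def _zy(p: np.ndarray) -> float:
    return float(p[2] - p[1])


def _pick_upper(tree: BranchTree, kids: list[int], result: ClassificationResult) -> tuple[int, int]:
    """Split two sibling subtrees into (upper, lower) by distal z; ties by
    smaller y (more anterior), logged."""
    a, b = kids
    za, zb = tree.distal_pos(a)[2], tree.distal_pos(b)[2]
    if za == zb:
        msg = "equal distal z among siblings; tie broken by smaller y"
        log.warning(msg)
        result.warnings.append(msg)
        ya, yb = tree.distal_pos(a)[1], tree.distal_pos(b)[1]
        return (a, b) if ya <= yb else (b, a)
    return (a, b) if za > zb else (b, a)


def _descend_single_child(tree: BranchTree, main: int, result: ClassificationResult) -> list[int]:
    """Resolve a main bronchus with a single child by looking one level deeper."""
    kids = tree.children[main]
    if len(kids) == 1:
        msg = f"branch {main} has a single child; using its children one level deeper"
        log.warning(msg)
        result.warnings.append(msg)
        return tree.children[kids[0]]
    return kids


def classify_lungs(tree: BranchTree) -> tuple[int, int]:
    """Identify (left_main, right_main) among the first-generation branches.

    Raises :class:`ClassificationError` when the trachea has fewer than two
    children — the side rule is then inapplicable and the case is reported.
    """
    first = tree.first_generation()
    if len(first) < 2:
        raise ClassificationError(
            f"trachea has {len(first)} first-generation branch(es); need 2"
        )
    xs = [tree.distal_pos(b)[0] for b in first]
    order = np.argsort(xs)  # larger x = patient left
    return first[int(order[-1])], first[int(order[0])]


def classify_left(
    tree: BranchTree, left_main: int, result: ClassificationResult
) -> None:
    """Label the left-lung subtree (LUL/LLL); left main inherits LLL."""
    labels = result.labels
    for b in tree.subtree_ids(left_main):
        labels[b] = LobeLabel.LLL
    kids = tree.children[left_main]
    if not kids:
        for b in tree.subtree_ids(left_main):
            labels[b] = LobeLabel.UNLABELED
        msg = "left main bronchus has no children; left lung left unlabeled"
        log.warning(msg)
        result.warnings.append(msg)
        return
    if len(kids) == 1:
        kids = _descend_single_child(tree, left_main, result)
        if len(kids) < 2:
            msg = "left lung has no second bifurcation; all left branches LLL"
            log.warning(msg)
            result.warnings.append(msg)
            return
    upper, _lower = _pick_upper(tree, kids, result)
    for b in tree.subtree_ids(upper):
        labels[b] = LobeLabel.LUL


def _split_rml_rll(
    tree: BranchTree, c_root: int, result: ClassificationResult
) -> None:
    """Apply the E/F rule to the right subtree rooted at branch `c_root`.

    Everything in the subtree defaults to RLL; the D-child subtree that
    contains the maximal-(z−y) terminal endpoint E becomes RML.  A subtree
    with no bifurcation (the middle-lobe airways are absent from the
    segmentation) stays all-RLL with a warning.
    """
    labels = result.labels
    sub = tree.subtree_ids(c_root)
    for b in sub:
        labels[b] = LobeLabel.RLL
    terminals = tree.terminal_branches(within=sub)
    if len(terminals) < 2:
        msg = (
            "right subtree below the intermedius has no bifurcation; "
            "RML airways appear absent — all branches labeled RLL"
        )
        log.warning(msg)
        result.warnings.append(msg)
        return
    scores = {b: _zy(tree.distal_pos(b)) for b in terminals}
    bE = max(terminals, key=lambda b: (scores[b], -b))
    bF = min(terminals, key=lambda b: (scores[b], b))
    result.landmarks["E"] = tree.distal_pos(bE).tolist()
    result.landmarks["F"] = tree.distal_pos(bF).tolist()

    # lowest common ancestor of the two terminal branches within the subtree
    def path_to_root(b: int) -> list[int]:
        path = [b]
        while path[-1] != c_root:
            path.append(tree.parent[path[-1]])
        return path

    pe, pf = path_to_root(bE), path_to_root(bF)
    fe = set(pf)
    lca = next(b for b in pe if b in fe)
    # D is the bifurcation where the E and F paths diverge
    result.landmarks["D"] = tree.distal_pos(lca).tolist()
    ie = pe.index(lca)
    if ie == 0:  # E's own branch is an ancestor of F: no distinct RML side
        msg = "E lies on F's path; RML/RLL split degenerate — all RLL"
        log.warning(msg)
        result.warnings.append(msg)
        return
    rml_head = pe[ie - 1]  # child of D on the path toward E
    for b in tree.subtree_ids(rml_head):
        labels[b] = LobeLabel.RML


def classify_right(
    tree: BranchTree, right_main: int, result: ClassificationResult
) -> None:
    """Label the right-lung subtree (RUL, then RML/RLL below node C)."""
    labels = result.labels
    for b in tree.subtree_ids(right_main):
        labels[b] = LobeLabel.RLL
    kids = tree.children[right_main]
    if not kids:
        for b in tree.subtree_ids(right_main):
            labels[b] = LobeLabel.UNLABELED
        msg = "right main bronchus has no children; right lung left unlabeled"
        log.warning(msg)
        result.warnings.append(msg)
        return
    if len(kids) == 1:
        kids = _descend_single_child(tree, right_main, result)
        if len(kids) < 2:
            msg = "right lung has no second bifurcation; all right branches RLL"
            log.warning(msg)
            result.warnings.append(msg)
            return
    rul_head, c_root = _pick_upper(tree, kids, result)
    for b in tree.subtree_ids(rul_head):
        labels[b] = LobeLabel.RUL
    result.landmarks["H"] = tree.distal_pos(rul_head).tolist()
    result.landmarks["C"] = tree.distal_pos(c_root).tolist()
    _split_rml_rll(tree, c_root, result)


def self_correct(
    tree: BranchTree,
    labels: dict[int, LobeLabel],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    result: ClassificationResult | None = None,
) -> dict[int, LobeLabel]:
    """Detect the short-BC topology exception and relabel the RUL.

    A = carina, B = distal node of the right main, C = distal node of the
    non-RUL child of the right main.  When BC/AB < `ratio_threshold`
    (strictly), the subtrees branching off at B and C both belong to the
    upper lobe: they are relabeled RUL and the RML/RLL rule is recomputed
    from the next node D.  Otherwise labels are returned unchanged.
    """
    if result is None:
        result = ClassificationResult(labels=dict(labels))
    else:
        result.labels = dict(labels)
    labels = result.labels
    try:
        left_main, right_main = classify_lungs(tree)
    except ClassificationError:
        log.warning("self_correct: cannot locate the right lung; skipped")
        return labels
    A = tree.node_pos(tree.proximal_node(right_main))
    B = tree.node_pos(tree.distal_node[right_main])
    kids = tree.children[right_main]
    if len(kids) < 2:
        log.info("self_correct: right main has <2 children; no correction")
        return labels
    rul_at_B, path_child = _pick_upper(tree, kids, result)
    C = tree.distal_pos(path_child)
    ab = float(np.linalg.norm(B - A))
    bc = float(np.linalg.norm(C - B))
    if ab <= 0:
        log.warning("self_correct: degenerate AB segment; skipped")
        return labels
    ratio = bc / ab
    result.landmarks.update(
        {"A": A.tolist(), "B": B.tolist(), "C_node": C.tolist(), "AB_mm": ab, "BC_mm": bc, "BC_over_AB": ratio}
    )
    if ratio >= ratio_threshold:  # strict inequality fires the correction
        return labels
    kids_c = tree.children[path_child]
    if len(kids_c) < 2:
        msg = "self_correct: node C has <2 children (missing node D); no correction"
        log.warning(msg)
        result.warnings.append(msg)
        return labels
    result.correction_fired = True
    msg = f"self-correction fired: BC/AB = {ratio:.3f} < {ratio_threshold}"
    log.info(msg)
    result.warnings.append(msg)
    rul_at_C, d_child = _pick_upper(tree, kids_c, result)
    for b in tree.subtree_ids(rul_at_B):
        labels[b] = LobeLabel.RUL
    for b in tree.subtree_ids(rul_at_C):
        labels[b] = LobeLabel.RUL
    labels[path_child] = LobeLabel.RLL
    labels[d_child] = LobeLabel.RLL
    _split_rml_rll(tree, d_child, result)
    return labels


def classify(
    tree: BranchTree,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    apply_correction: bool = True,
) -> ClassificationResult:
    """Run the full rule set (+ optional self-correction) on a branch tree."""
    result = ClassificationResult(labels={})
    result.labels[tree.root_id] = LobeLabel.TRACHEA
    left_main, right_main = classify_lungs(tree)
    result.landmarks["B_left_distal"] = tree.distal_pos(left_main).tolist()
    result.landmarks["M_right_distal"] = tree.distal_pos(right_main).tolist()
    classify_left(tree, left_main, result)
    classify_right(tree, right_main, result)
    # orphan fragments disconnected from the trachea stay unlabeled
    for bid in tree.branch_ids():
        result.labels.setdefault(bid, LobeLabel.UNLABELED)
    if apply_correction:
        result.labels = self_correct(tree, result.labels, ratio_threshold, result)
    return result
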