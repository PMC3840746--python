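"""Marker-based distances and neighbor-joining trees.

Distances are computed from pairwise global alignments of the extracted
markers (p-distance, optionally Jukes-Cantor corrected) rather than from a
multiple alignment: the pairwise route is fully specified and exactly
testable, and at the divergences the markers show the resulting trees are
equivalent for qualitative grouping.

Neighbor joining is the canonical agglomerative algorithm and is exact on
additive distance matrices; negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch, the usual convention.
Trees are :class:`skbio.TreeNode` objects (unrooted, represented with a
trifurcating root) serialized to Newick with 6 significant digits.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .marker import Scoring, global_align
from .seqio import SequenceSet

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "nj_tree",
    "write_newick",
    "read_newick",
    "cut_clusters",
]

_MODEL_ALIASES = {
    "p": "p_distance", "p_distance": "p_distance",
    "jc": "jukes_cantor", "jukes_cantor": "jukes_cantor",
}


def _pairwise_p(a: str, b: str, scoring: Scoring) -> float:
    # canonical argument order: co-optimal alignments can differ in gap
    # placement, and the mismatch fraction must not depend on input order
    if a > b:
        a, b = b, a
    aln = global_align(a, b, scoring)
    compared = mismatched = 0
    for x, y in aln.columns():
        if x != "-" and y != "-":
            compared += 1
            if x != y:
                mismatched += 1
    if compared == 0:
        raise ValueError("no comparable columns between sequences")
    return mismatched / compared


def jukes_cantor(p: float) -> float:
    """JC69 correction -(3/4) ln(1 - 4p/3); undefined for p >= 0.75."""
    if p >= 0.75:
        raise ValueError(f"p-distance {p} >= 0.75: Jukes-Cantor undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def distance_matrix(markers: SequenceSet, model: str = "p_distance",
                    scoring: Scoring = Scoring()) -> DistanceMatrix:
    """Pairwise marker distances (gap columns excluded from the counts)."""
    try:
        model = _MODEL_ALIASES[model]
    except KeyError:
        raise ValueError(f"unknown distance model {model!r}") from None
    n = len(markers)
    if n < 2:
        raise ValueError("need at least two sequences")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(markers[i].residues, markers[j].residues, scoring)
            d = jukes_cantor(p) if model == "jukes_cantor" else p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=markers.ids)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q-criterion break deterministically toward the pair with
    the smallest (row, column) index in the current working order (original
    label order, merged nodes appended last).  The final three nodes are
    joined at an unrooted (trifurcating) root with three-point limb lengths.
    """
    labels = list(d.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    D = np.array(d.data, dtype=float)

    while len(nodes) > 3:
        n = len(D)
        r = D.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = du[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [u]

    (a, b, c), M = nodes, D
    la = 0.5 * (M[0, 1] + M[0, 2] - M[1, 2])
    lb = 0.5 * (M[0, 1] + M[1, 2] - M[0, 2])
    lc = 0.5 * (M[0, 2] + M[1, 2] - M[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def _newick(node: TreeNode) -> str:
    if node.is_tip():
        s = node.name or ""
    else:
        s = "(" + ",".join(_newick(c) for c in node.children) + ")"
        if node.name:
            s += node.name
    if node.length is not None:
        s += ":%.6g" % node.length
    return s


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize with branch lengths at 6 significant digits."""
    Path(path).write_text(_newick(tree) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific parse errors
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc


def cut_clusters(tree: TreeNode, k: int) -> list[set[str]]:
    """Partition the leaves by removing the k-1 longest internal edges.

    Internal edges are branches below internal (non-root, non-tip) nodes;
    ties in length break by preorder traversal order.  Clusters are
    returned in order of their first leaf in the tree's tip order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    internal = [nd for nd in tree.preorder(include_self=False) if not nd.is_tip()]
    if k - 1 > len(internal):
        raise ValueError(f"tree has only {len(internal)} internal edges; "
                         f"cannot cut into {k} clusters")
    cut = set()
    for nd in sorted(internal, key=lambda nd: -(nd.length or 0.0))[: k - 1]:
        cut.add(id(nd))

    clusters: dict[int | None, set[str]] = {}
    order: list[int | None] = []
    for tip in tree.tips():
        anc = tip.parent
        key = None
        while anc is not None:
            if id(anc) in cut:
                key = id(anc)
                break
            anc = anc.parent
        if key not in clusters:
            clusters[key] = set()
            order.append(key)
        clusters[key].add(tip.name)
    return [clusters[key] for key in order]
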