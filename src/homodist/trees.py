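"""Distance-tree construction: neighbor joining and UPGMA.

Both builders consume a :class:`~homodist.distances.DistanceMatrix` and
return a ``skbio.TreeNode``.  UPGMA trees are rooted and ultrametric by
construction; NJ trees are unrooted and stored with the conventional
trifurcating root.  Parsimony scoring downstream consumes the topology
only, and the Fitch length is invariant to rooting for unordered
characters, so the arbitrary NJ rooting is harmless.

Determinism contract: agglomeration ties are broken by the lowest
(row, column) index pair of the working matrix, where a merged cluster
takes the row of its lower-indexed member; Newick output orders children
by their smallest contained leaf label.  Runs are therefore exactly
reproducible and per-step tree files are diffable.

Negative NJ branch lengths (possible on non-additive input) are kept on
the in-memory tree for diagnostics and clamped to zero at serialization.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from homodist.distances import DistanceMatrix, DistanceError


def _check(D: DistanceMatrix, min_taxa: int, what: str) -> None:
    if D.n < min_taxa:
        raise DistanceError(f"{what} needs >= {min_taxa} taxa, got {D.n}")
    if D.has_undefined:
        pairs = ", ".join(f"{a}/{b}" for a, b in D.undefined_pairs)
        raise DistanceError(
            f"{what} cannot run with undefined (saturated) distances: {pairs}"
        )


def _argmin_pair(m: np.ndarray) -> tuple[int, int]:
    """Index pair (i<j) of the minimum of an upper-triangle criterion.

    ``np.argmin`` scans row-major, so exact ties resolve to the lowest
    (row, column) pair — the documented tie-break.
    """
    n = m.shape[0]
    masked = m.copy()
    masked[np.tril_indices(n)] = np.inf
    flat = int(np.argmin(masked))
    return flat // n, flat % n


def build_nj(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating root
    (three children at the top level for n >= 4; for n == 3 the single
    internal node with the three-point branch lengths).
    """
    _check(D, 3, "neighbor joining")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    d = D.values.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        i, j = _argmin_pair(q)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        merged = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = merged
        del nodes[j]
    # final three-point join: l_k = (d_kx + d_ky - d_xy) / 2
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = length
    return TreeNode(children=list(nodes))


def build_upgma(D: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering into a rooted ultrametric tree.

    Node heights are half the average inter-cluster distance at each
    merge; merge heights are nondecreasing for any valid input.
    """
    _check(D, 2, "UPGMA")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    heights = [0.0] * D.n
    sizes = [1] * D.n
    d = D.values.astype(float).copy()
    while len(nodes) > 1:
        n = len(nodes)
        i, j = _argmin_pair(d)
        h = 0.5 * d[i, j]
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        merged = TreeNode(children=[nodes[i], nodes[j]])
        new_row = (sizes[i] * d[i, :] + sizes[j] * d[j, :]) / (sizes[i] + sizes[j])
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = merged
        heights[i] = h
        sizes[i] = sizes[i] + sizes[j]
        del nodes[j]
        del heights[j]
        del sizes[j]
    return nodes[0]


_NEWICK_RESERVED = set("(),:;'[] \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_RESERVED:
        return "'" + label.replace("'", "''") + "'"
    return label


def _min_leaf(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(_min_leaf(c) for c in node.children)


def _serialize(node: TreeNode, clamp: bool) -> str:
    if node.is_tip():
        body = _quote(node.name)
    else:
        children = sorted(node.children, key=_min_leaf)
        body = "(" + ",".join(_serialize(c, clamp) for c in children) + ")"
    if node.length is not None:
        length = max(0.0, node.length) if clamp else node.length
        body += f":{length:.10g}"
    return body


def to_newick(tree: TreeNode, clamp_negative: bool = True) -> str:
    """Serialize to Newick with deterministic child ordering.

    Children are ordered by smallest contained leaf label; labels with
    reserved characters are quoted; negative branch lengths are clamped
    to zero unless ``clamp_negative`` is false.
    """
    return _serialize(tree, clamp_negative) + ";"


def leaf_names(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def unrooted_splits(tree: TreeNode) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology.

    Each split is canonicalised as the side not containing the
    lexicographically smallest leaf, so rooted and unrooted encodings of
    the same topology compare equal.  Two trees over the same leaf set
    have the same unrooted topology iff their split sets are equal.
    """
    leaves = frozenset(leaf_names(tree))
    anchor = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        if anchor in side:
            side = leaves - side
        splits.add(side)
    return frozenset(splits)


def same_unrooted_topology(a: TreeNode, b: TreeNode) -> bool:
    """True when two trees over the same leaf set share every bipartition."""
    la, lb = frozenset(leaf_names(a)), frozenset(leaf_names(b))
    if la != lb:
        return False
    return unrooted_splits(a) == unrooted_splits(b)
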