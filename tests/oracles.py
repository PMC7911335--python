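"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: parsimony by
exhaustive enumeration of ancestral states, and tree topology by
brute-force enumeration of all unrooted binary shapes with a
least-squares branch-length fit.
"""

from __future__ import annotations

import collections
import itertools
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from homodist.parsimony import STATE_MASK

_STATES = "ACGT"


def _mask_to_states(mask: int) -> list[str]:
    return [s for i, s in enumerate(_STATES) if mask >> i & 1]


def exhaustive_min_steps(tree: TreeNode, column: Mapping[str, str]) -> int:
    """Minimum changes by brute force over all ancestral assignments.

    Every internal node tries all four states; every leaf tries every
    state its (possibly ambiguous) character admits; the cost is the
    number of edges whose endpoints differ.  Exponential — for tiny
    trees only.
    """
    nodes = list(tree.postorder(include_self=True))
    internals = [n for n in nodes if not n.is_tip()]
    leaves = [n for n in nodes if n.is_tip()]
    leaf_choices = [_mask_to_states(STATE_MASK[column[n.name]]) for n in leaves]
    best = float("inf")
    for internal_assign in itertools.product(_STATES, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, internal_assign)}
        cost = sum(
            1
            for n in internals
            if n.parent is not None and state[id(n)] != state[id(n.parent)]
        )
        if cost >= best:
            continue
        for leaf, choices in zip(leaves, leaf_choices):
            parent_state = state[id(leaf.parent)]
            cost += min(1 if c != parent_state else 0 for c in choices)
        best = min(best, cost)
    return int(best)


def enumerate_unrooted_edge_lists(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from ``n`` upward.  Counts follow
    (2n-5)!!: 1, 3, 15, 105 for n = 3..6.
    """
    trees: list[tuple[list[tuple[int, int]], int]] = [
        ([(n, 0), (n, 1), (n, 2)], n + 1)
    ]
    for leaf in range(3, n):
        nxt_trees = []
        for edges, nxt in trees:
            for idx, (u, v) in enumerate(edges):
                grown = edges[:idx] + edges[idx + 1:]
                grown += [(u, nxt), (nxt, v), (nxt, leaf)]
                nxt_trees.append((grown, nxt + 1))
        trees = nxt_trees
    return [edges for edges, _ in trees]


def _adjacency(edges: Sequence[tuple[int, int]]) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = collections.defaultdict(set)
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def edge_list_splits(edges: Sequence[tuple[int, int]], n: int) -> frozenset[frozenset[int]]:
    """Non-trivial splits (canonical: the side without leaf 0)."""
    adj = _adjacency(edges)
    splits = set()
    all_leaves = frozenset(range(n))
    for u, v in edges:
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if {x, y} == {u, v}:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(l for l in range(n) if l in seen)
        if 2 <= len(side) <= n - 2:
            if 0 in side:
                side = all_leaves - side
            splits.add(side)
    return frozenset(splits)


def _pair_paths(edges: Sequence[tuple[int, int]], n: int) -> list[list[int]]:
    """For each leaf pair (i<j), the indices of edges on the path."""
    adj: dict[int, list[tuple[int, int]]] = collections.defaultdict(list)
    for e_idx, (u, v) in enumerate(edges):
        adj[u].append((v, e_idx))
        adj[v].append((u, e_idx))
    paths = []
    for i in range(n):
        # BFS from leaf i recording the edge trail
        trail: dict[int, list[int]] = {i: []}
        queue = collections.deque([i])
        while queue:
            x = queue.popleft()
            for y, e_idx in adj[x]:
                if y not in trail:
                    trail[y] = trail[x] + [e_idx]
                    queue.append(y)
        for j in range(i + 1, n):
            paths.append(trail[j])
    return paths


def least_squares_residual(
    edges: Sequence[tuple[int, int]], n: int, D: np.ndarray
) -> float:
    """Residual of the best nonneg-free LS branch-length fit of D."""
    paths = _pair_paths(edges, n)
    X = np.zeros((len(paths), len(edges)))
    y = []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            for e_idx in paths[k]:
                X[k, e_idx] = 1.0
            y.append(D[i, j])
            k += 1
    y = np.asarray(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.linalg.norm(X @ coef - y))


def best_topology_by_least_squares(D: np.ndarray) -> frozenset[frozenset[int]]:
    """Splits of the unique minimal-residual topology for matrix D."""
    n = D.shape[0]
    best = None
    best_res = float("inf")
    for edges in enumerate_unrooted_edge_lists(n):
        res = least_squares_residual(edges, n, D)
        if res < best_res:
            best_res = res
            best = edge_list_splits(edges, n)
    return best


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Textbook product-moment correlation."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))


def k80_reference_grid_point(P: float, Q: float) -> float:
    """Independent K80 transcription used by the F84 reduction check."""
    import math

    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
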