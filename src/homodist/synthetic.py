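"""Synthetic alignments with known, controllable homoplasy.

Three generators back the test suite and demos:

* a homoplasy-free constructor: every variable site marks exactly one
  edge of a known tree (all taxa below the edge carry one derived
  state), so on the generating topology each variable site fits with
  exactly one change and CI = 1 holds *by construction*, not
  probabilistically;
* a convergence injector: appends sites whose derived state is shared
  by two disjoint, non-adjacent clades, so each such site needs at
  least two changes on the true tree while its minimum is one —
  guaranteed homoplasy with a known lower bound;
* a Markov simulator of the F84 substitution process along branches,
  used to check that the closed-form pairwise distance recovers path
  lengths.

All generators are deterministic per seed.  Convergent evolution (not
horizontal-transfer-style segment swaps) is the injection mechanism: it
is the simplest construction with a provable per-site step bound.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm
from skbio import TreeNode

from homodist.alignment import Alignment
from homodist.distances import BaseFrequencies
from homodist.trees import unrooted_splits

_BASES = np.array(list("ACGT"))


class SyntheticError(ValueError):
    """Raised when a generator precondition fails."""


def random_binary_tree(
    n_taxa: int,
    seed: int,
    mean_branch_length: float = 0.05,
    prefix: str = "t",
) -> TreeNode:
    """Random rooted binary topology with exponential branch lengths.

    Coalescent-style construction: starting from ``n_taxa`` labelled
    tips (``t0`` .. ``t{n-1}``), repeatedly join two uniformly chosen
    lineages until one remains.  Deterministic per seed.
    """
    if n_taxa < 3:
        raise SyntheticError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"{prefix}{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.exponential(mean_branch_length))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.exponential(mean_branch_length))
        nodes[i] = parent
        del nodes[j]
    root = nodes[0]
    root.length = None
    return root


def _clade_leafsets(tree: TreeNode) -> list[tuple[TreeNode, frozenset[str]]]:
    """(node, leaf set) for every non-root node, in postorder."""
    out = []
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = frozenset([node.name])
        else:
            sets[id(node)] = frozenset().union(*(sets[id(c)] for c in node.children))
        if node.parent is not None:
            out.append((node, sets[id(node)]))
    return out


def simulate_homoplasy_free_alignment(
    tree: TreeNode,
    n_sites: int,
    n_mutations: int,
    seed: int,
) -> Alignment:
    """Alignment in which every variable site fits the tree in one step.

    ``n_mutations`` distinct sites each get one uniformly chosen edge
    (non-root node): the taxa below it receive a derived base, everyone
    else keeps the site's ancestral base.  The remaining sites are
    invariant.  Scored on the generating topology this gives S = M and
    CI = 1 exactly.
    """
    if n_mutations > n_sites:
        raise SyntheticError("n_mutations cannot exceed n_sites")
    rng = np.random.default_rng(seed)
    labels = tuple(tip.name for tip in tree.tips())
    n = len(labels)
    ancestral = rng.integers(0, 4, size=n_sites)
    matrix = np.tile(ancestral, (n, 1))
    clades = _clade_leafsets(tree)
    sites = rng.choice(n_sites, size=n_mutations, replace=False)
    label_index = {lab: i for i, lab in enumerate(labels)}
    for j in sites:
        _, leafset = clades[rng.integers(len(clades))]
        derived = (ancestral[j] + rng.integers(1, 4)) % 4
        for lab in leafset:
            matrix[label_index[lab], j] = derived
    rows = tuple("".join(_BASES[r]) for r in matrix)
    return Alignment(labels, rows)


def inject_convergent_sites(
    aln: Alignment,
    tree: TreeNode,
    k: int,
    seed: int,
) -> Alignment:
    """Append ``k`` convergent sites guaranteeing homoplasy on ``tree``.

    Each appended site gives the same derived state to two disjoint
    clades whose union is not a bipartition side of the unrooted tree,
    so the site needs >= 2 changes on the true topology while its
    minimum over all trees is 1.  Raises if the tree offers no such
    clade pair.
    """
    if k < 1:
        raise SyntheticError("k must be >= 1")
    leaves = frozenset(tip.name for tip in tree.tips())
    if frozenset(aln.labels) != leaves:
        raise SyntheticError("alignment labels must equal tree leaves")
    splits = unrooted_splits(tree)
    anchor = min(leaves)

    def is_split(side: frozenset[str]) -> bool:
        if len(side) < 2 or len(leaves - side) < 2:
            return True  # trivial splits are present in every tree
        canon = (leaves - side) if anchor in side else side
        return canon in splits

    clades = [s for _, s in _clade_leafsets(tree)]
    candidates = [
        (a, b)
        for i, a in enumerate(clades)
        for b in clades[i + 1:]
        if not (a & b) and (a | b) != leaves and not is_split(a | b)
    ]
    if not candidates:
        raise SyntheticError("tree has no pair of disjoint non-adjacent clades")
    rng = np.random.default_rng(seed)
    extra_cols = []
    for _ in range(k):
        a, b = candidates[rng.integers(len(candidates))]
        ancestral = rng.integers(0, 4)
        derived = (ancestral + rng.integers(1, 4)) % 4
        col = {
            lab: _BASES[derived] if lab in (a | b) else _BASES[ancestral]
            for lab in aln.labels
        }
        extra_cols.append(col)
    rows = tuple(
        row + "".join(col[lab] for col in extra_cols)
        for lab, row in zip(aln.labels, aln.rows)
    )
    return Alignment(aln.labels, rows)


def f84_rate_matrix(freqs: BaseFrequencies, kappa: float = 2.0) -> np.ndarray:
    """F84 instantaneous rate matrix, normalised to one substitution
    per site per unit branch length.

    Off-diagonal rate to base j is pi_j for transversions and
    pi_j * (1 + kappa / pi_group(j)) for transitions, where pi_group is
    the purine or pyrimidine frequency sum of the target base.
    """
    pi = freqs.as_array()
    groups = np.array([freqs.pi_R, freqs.pi_Y, freqs.pi_R, freqs.pi_Y])
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i % 2) == (j % 2)
            Q[i, j] = pi[j] * (1.0 + kappa / groups[j]) if transition else pi[j]
        Q[i, i] = -Q[i].sum()
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def simulate_f84_sequences(
    tree: TreeNode,
    freqs: BaseFrequencies,
    kappa: float,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Evolve sequences down ``tree`` under the F84 Markov process.

    The root sequence is drawn from the stationary frequencies; each
    branch applies the transition matrix expm(Q * length).  Branch
    lengths are expected substitutions per site.
    """
    rng = np.random.default_rng(seed)
    Q = f84_rate_matrix(freqs, kappa)
    root_seq = rng.choice(4, size=n_sites, p=freqs.as_array())
    states: dict[int, np.ndarray] = {id(tree): root_seq}
    rows: dict[str, str] = {}
    order: list[str] = []
    for node in tree.preorder(include_self=True):
        if node.parent is not None:
            parent_seq = states[id(node.parent)]
            P = expm(Q * (node.length or 0.0))
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            u = rng.random(n_sites)
            cum = P.cumsum(axis=1)[parent_seq]
            seq = (u[:, None] > cum).sum(axis=1)
            states[id(node)] = seq
        if node.is_tip():
            rows[node.name] = "".join(_BASES[states[id(node)]])
            order.append(node.name)
    return Alignment(tuple(order), tuple(rows[lab] for lab in order))
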