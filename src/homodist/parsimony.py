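"""Fitch parsimony site scoring and the homoplasy indices CI, RI, HI, RCI.

Characters are unordered nucleotide states.  Gaps and ``?`` are missing
data: such a leaf carries the full {A,C,G,T} state set and never forces
a change.  IUPAC ambiguity codes carry their base set.

Per site, three step counts are defined over the taxa in the tree:

* ``s`` — the minimum number of changes the site requires on the given
  topology (Fitch 1971 for bifurcating nodes, Hartigan's frequency-count
  generalisation at multifurcations such as the NJ root trifurcation, so
  the count is exact on every tree this package builds);
* ``m`` — the minimum conceivable on any tree: (number of distinct
  unambiguous states) - 1;
* ``g`` — the maximum needed on any tree: the Fitch length of the
  completely unresolved star tree.  With no partial-ambiguity codes
  this is the familiar (number of taxa with an unambiguous base) -
  (multiplicity of the most frequent state); scoring the star tree
  under the same state-set semantics as ``s`` keeps s <= g even when
  codes like R or Y are present.

Summing over sites gives S, M, G and the indices

    CI = M / S   (consistency; CI := 1 when S = 0)
    HI = 1 - CI  (homoplasy)
    RI = (G - S) / (G - M)   (retention; not available when G = M)
    RCI = CI * RI            (rescaled consistency)

CI is computed over all sites, parsimony-uninformative ones included
(they contribute equally to M and S, so the convention only matters when
reconciling with tools that exclude them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from skbio import TreeNode

from homodist.alignment import Alignment

#: IUPAC character -> bitmask over (A=1, C=2, G=4, T=8).
STATE_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15,
}

_UNAMBIGUOUS = {"A": 0, "C": 1, "G": 2, "T": 3}


class ParsimonyError(ValueError):
    """Raised on tree/character mismatches."""


def _encode_rows(aln: Alignment) -> dict[str, np.ndarray]:
    """Per-taxon uint8 state-mask arrays over all sites."""
    lut = np.zeros(128, dtype=np.uint8)
    for ch, mask in STATE_MASK.items():
        lut[ord(ch)] = mask
    return {
        lab: lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        for lab, row in zip(aln.labels, aln.rows)
    }


def _hartigan_steps(tree: TreeNode, leaf_masks: Mapping[str, np.ndarray]) -> np.ndarray:
    """Minimum changes per site on ``tree``, vectorised across sites.

    Bottom-up pass: at each internal node, count for every state how
    many children admit it; the node keeps the argmax states and pays
    (number of children - max count) changes.  Equivalent to Fitch
    intersection/union at bifurcations and exact at multifurcations.
    """
    first = next(iter(leaf_masks.values()))
    n_sites = first.shape[0]
    steps = np.zeros(n_sites, dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            try:
                masks[id(node)] = leaf_masks[node.name]
            except KeyError:
                raise ParsimonyError(
                    f"tree leaf {node.name!r} has no character data"
                ) from None
        else:
            counts = np.zeros((n_sites, 4), dtype=np.int16)
            for child in node.children:
                cm = masks.pop(id(child))
                for s in range(4):
                    counts[:, s] += (cm >> s) & 1
            kmax = counts.max(axis=1)
            steps += len(node.children) - kmax
            node_mask = np.zeros(n_sites, dtype=np.uint8)
            for s in range(4):
                node_mask |= ((counts[:, s] == kmax).astype(np.uint8)) << s
            masks[id(node)] = node_mask
    return steps


def fitch_site_steps(tree: TreeNode, column: Mapping[str, str]) -> int:
    """Minimum number of changes one site requires on ``tree``.

    ``column`` maps taxon label to a single IUPAC character; taxa absent
    from the tree are ignored, a tree leaf absent from the column is an
    error.  The count is invariant to the rooting of the topology.
    """
    leaf_masks = {}
    for lab, ch in column.items():
        if ch not in STATE_MASK:
            raise ParsimonyError(f"invalid character {ch!r} for taxon {lab!r}")
        leaf_masks[lab] = np.array([STATE_MASK[ch]], dtype=np.uint8)
    return int(_hartigan_steps(tree, leaf_masks)[0])


def site_min_steps(column: Mapping[str, str]) -> int:
    """Minimum changes on any tree: distinct unambiguous states - 1."""
    observed = {ch for ch in column.values() if ch in _UNAMBIGUOUS}
    return max(0, len(observed) - 1)


def site_max_steps(column: Mapping[str, str]) -> int:
    """Maximum changes needed on any tree (star-tree Fitch length).

    Computed with the same state-set semantics as the tree score:
    steps = n_taxa - max over states of (taxa whose set admits the
    state).  Missing-data taxa admit every state and contribute
    nothing; with unambiguous bases only, this equals n_scored minus
    the multiplicity of the most frequent state.
    """
    admits = np.zeros(4, dtype=int)
    n = 0
    for ch in column.values():
        mask = STATE_MASK.get(ch)
        if mask is None:
            raise ParsimonyError(f"invalid character {ch!r}")
        n += 1
        for s in range(4):
            admits[s] += (mask >> s) & 1
    if n == 0:
        return 0
    return n - int(admits.max())


@dataclass(frozen=True)
class ParsimonyScores:
    """Alignment-wide step totals and the derived homoplasy indices."""

    S: int
    M: int
    G: int

    def __post_init__(self) -> None:
        if not (self.M <= self.S <= self.G or self.S == 0):
            raise ParsimonyError(
                f"step totals violate M <= S <= G: M={self.M} S={self.S} G={self.G}"
            )

    @property
    def ci(self) -> float:
        """Consistency index M/S, with CI := 1 for a homoplasy-free or
        invariant alignment (S = 0)."""
        if self.S == 0:
            return 1.0
        return self.M / self.S

    @property
    def hi(self) -> float:
        return 1.0 - self.ci

    @property
    def ri(self) -> Optional[float]:
        """Retention index (G-S)/(G-M); None when undefined (G = M)."""
        if self.G == self.M:
            return None
        return (self.G - self.S) / (self.G - self.M)

    @property
    def rci(self) -> Optional[float]:
        ri = self.ri
        if ri is None:
            return None
        return self.ci * ri


def consistency_indices(tree: TreeNode, aln: Alignment) -> ParsimonyScores:
    """Score every site of ``aln`` on ``tree`` and sum S, M, G.

    The tree's leaf set must equal the alignment's label set.
    """
    tree_leaves = {tip.name for tip in tree.tips()}
    if tree_leaves != set(aln.labels):
        missing = tree_leaves - set(aln.labels)
        extra = set(aln.labels) - tree_leaves
        raise ParsimonyError(
            f"tree/alignment label mismatch (tree-only: {sorted(missing)}, "
            f"alignment-only: {sorted(extra)})"
        )
    leaf_masks = _encode_rows(aln)
    steps = _hartigan_steps(tree, leaf_masks)
    S = int(steps.sum())

    # vectorised M (distinct unambiguous states - 1 per column)
    codes = np.full((aln.n_taxa, aln.n_sites), -1, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        arr = np.frombuffer(row.encode("ascii"), dtype="S1")
        for base, code in _UNAMBIGUOUS.items():
            codes[i][arr == base.encode()] = code
    counts = np.stack([(codes == c).sum(axis=0) for c in range(4)])  # (4, sites)
    n_states = (counts > 0).sum(axis=0)
    M = int(np.maximum(0, n_states - 1).sum())

    # vectorised G: star-tree length n_taxa - max state admissibility
    mask_stack = np.stack([leaf_masks[lab] for lab in aln.labels])  # (taxa, sites)
    admits = np.stack([((mask_stack >> s) & 1).sum(axis=0) for s in range(4)])
    G = int((aln.n_taxa - admits.max(axis=0)).sum())
    return ParsimonyScores(S=S, M=M, G=G)
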