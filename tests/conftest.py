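"""Shared fixtures: hand-constructed alignments with known homoplasy.

Both fixtures are built column by column from a known tree: every
clean site marks exactly one clade (a derived state below one edge),
so raw pairwise distances are exactly additive on the tree with
integer edge weights, neighbor joining provably recovers the topology
on every taxon subset, and appended convergent sites create homoplasy
at a step known by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pytest
from hypothesis import settings
from skbio import TreeNode

from homodist.alignment import Alignment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

_DERIVED = "CGT"


def marker_alignment(labels: tuple[str, ...], markers: list[frozenset]) -> Alignment:
    """One column per marker set: derived base inside, 'A' outside.

    Derived bases cycle over C/G/T so more than two bases occur overall.
    """
    cols = []
    for i, clade in enumerate(markers):
        d = _DERIVED[i % 3]
        cols.append({lab: (d if lab in clade else "A") for lab in labels})
    rows = tuple("".join(col[lab] for col in cols) for lab in labels)
    return Alignment(labels, rows)


@dataclass(frozen=True)
class ConvergentFixture:
    """Eight taxa, additive clean signal plus one convergent site.

    True rooted topology (((t0,t1),(t2,t3)),((t4,t5),(t6,t7))) with
    integer site weights per edge; the convergent site gives the same
    derived state to the non-adjacent clades {t2,t3} and {t6,t7}.
    With raw distances the center is t0 and the series is t0..t7 in
    order, so homoplasy first appears at the step that adds t6
    (step 4 of 5): only then does the convergent site's derived set
    split into two blocks on the restricted true topology.
    """

    alignment: Alignment
    tree: TreeNode
    labels: tuple[str, ...]
    n_sites: int
    expected_series: tuple[str, ...]
    first_homoplasy_step_index: int
    expected_sm: tuple[tuple[int, int], ...]  # exact (S, M) per step


def _convergent_fixture() -> ConvergentFixture:
    labels = tuple(f"t{i}" for i in range(8))
    leaf_w = {f"t{i}": i + 1 for i in range(8)}
    markers: list[frozenset] = []
    for lab, w in leaf_w.items():
        markers += [frozenset([lab])] * w
    cherries = [("t0", "t1"), ("t2", "t3"), ("t4", "t5"), ("t6", "t7")]
    for pair in cherries:
        markers += [frozenset(pair)] * 2
    markers += [frozenset(["t0", "t1", "t2", "t3"])] * 3
    markers += [frozenset(["t4", "t5", "t6", "t7"])] * 3
    # the convergent site: same derived state in two separated clades
    markers += [frozenset(["t2", "t3", "t6", "t7"])]
    aln = marker_alignment(labels, markers)
    tree = TreeNode.read(io.StringIO("(((t0,t1),(t2,t3)),((t4,t5),(t6,t7)));"))

    # Exact (S, M) per step on the true restricted topology.  A clean
    # site is variable in subset {t0..t(k-1)} iff its clade is neither
    # empty nor the whole subset after restriction; every variable
    # clean site costs exactly one step.  The convergent site costs one
    # step until t6 joins (its derived taxa then fall in two blocks)
    # and two steps afterwards.
    def clean_variable(k: int) -> int:
        lost = sum(leaf_w[f"t{i}"] for i in range(k, 8))
        absent = {f"t{i}" for i in range(k, 8)}
        for pair in cherries:
            if set(pair) <= absent:
                lost += 2
        if {"t4", "t5", "t6", "t7"} <= absent:
            lost += 3  # right stem invariant
        if k == 4:
            lost += 3  # left stem covers the whole subset: monomorphic
        return 50 - lost

    expected_sm = []
    for k in range(4, 9):
        base = clean_variable(k)
        s = base + (2 if k >= 7 else 1)
        m = base + 1
        expected_sm.append((s, m))
    return ConvergentFixture(
        alignment=aln,
        tree=tree,
        labels=labels,
        n_sites=aln.n_sites,
        expected_series=labels,
        first_homoplasy_step_index=4,
        expected_sm=tuple(expected_sm),
    )


@pytest.fixture(scope="session")
def convergent_fixture() -> ConvergentFixture:
    return _convergent_fixture()


@dataclass(frozen=True)
class SpeciesBlocksFixture:
    """Three congruent 'species' of three strains each, then two
    distant taxa; a convergent site ties species B to taxon x1.

    All sites within the nine-strain prefix are clade markers on the
    true topology and the prefix distances are additive, so CI = 1 must
    hold over the prefix; homoplasy appears exactly when x1 enters.
    """

    alignment: Alignment
    tree: TreeNode
    species: dict[str, tuple[str, ...]]
    prefix_len: int  # taxa covered by the CI = 1 prefix
    homoplasy_taxon: str  # first taxon whose addition creates HI > 0


def _species_blocks_fixture() -> SpeciesBlocksFixture:
    species = {
        "A": ("a1", "a2", "a3"),
        "B": ("b1", "b2", "b3"),
        "C": ("c1", "c2", "c3"),
    }
    labels = species["A"] + species["B"] + species["C"] + ("x1", "x2")
    markers: list[frozenset] = []
    # private strain sites (block leaders get none, so a1 is the center)
    for block in species.values():
        for j, lab in enumerate(block):
            markers += [frozenset([lab])] * j
    markers += [frozenset(["x1"])] * 8
    markers += [frozenset(["x2"])] * 10
    # within-species cherries
    for block in species.values():
        markers += [frozenset(block[1:])]
    # species stems staggered so the series orders A < B < C < x
    markers += [frozenset(species["B"])] * 4
    markers += [frozenset(species["C"])] * 8
    markers += [frozenset(("x1", "x2"))] * 20
    markers += [frozenset(species["C"] + ("x1", "x2"))] * 2
    # convergent site: species B and the distant x1 share a derived state
    markers += [frozenset(species["B"] + ("x1",))]
    aln = marker_alignment(labels, markers)
    tree = TreeNode.read(
        io.StringIO("(((a1,(a2,a3)),(b1,(b2,b3))),((c1,(c2,c3)),(x1,x2)));")
    )
    return SpeciesBlocksFixture(
        alignment=aln, tree=tree, species=species, prefix_len=9,
        homoplasy_taxon="x1",
    )


@pytest.fixture(scope="session")
def species_blocks_fixture() -> SpeciesBlocksFixture:
    return _species_blocks_fixture()
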