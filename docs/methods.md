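# Methods

This note documents the models, conventions and numerical choices
behind `homodist`, and what the synthetic tests do and do not show
about real data.

## The trace procedure

The engine consumes a single aligned DNA matrix (equal-length rows,
IUPAC codes, gaps allowed) and is fully deterministic: there is no
random number source anywhere in the pipeline, and all ties resolve by
documented rules keyed to input order. The full distance matrix is
computed once and sliced per step; under pairwise deletion a pairwise
distance does not depend on which other taxa are present, so slicing
and recomputation are equivalent.

The center is the taxon minimising the mean distance to all others
(ties: earliest in input order). The series orders the remaining taxa
by increasing distance from the center with a stable sort, so taxa at
equal distance keep their input order. Step 1 scores the first
four-taxon tree (center plus three nearest); no indices are reported
for two- or three-taxon subsets, where parsimony indices are
degenerate. Step 1's `disCen` is the third-closest taxon's distance;
every later step records the added taxon's distance. Both `disCen` and
`MaxD` are nondecreasing along the trace by construction.

Indices are computed on both the neighbor-joining and the UPGMA tree
of each subset and reported side by side; the headline method is NJ,
the field-standard distance tree, and the downstream analyses take the
method as a parameter. Distances are substitutions per site
internally; percent scales belong to presentation.

## Distance models

**F84** (unequal base frequencies, transition/transversion
distinction) is the default. With transition and transversion
proportions P and Q, frequencies pi, piR = piA+piG, piY = piC+piT and

    A = piC*piT/piY + piA*piG/piR,  B = piC*piT + piA*piG,  C = piR*piY,

the distance is

    d = -2A ln(1 - P/(2A) - (A-B)Q/(2AC)) + 2(A-B-C) ln(1 - Q/(2C)).

The transcription is guarded by two independent checks: algebraically
the form must collapse to the Kimura two-parameter distance when the
frequencies are uniform (asserted to 1e-10 on a (P,Q) grid against a
separate K80 transcription), and the estimator must recover the true
path length of sequences simulated under the F84 Markov process
(two-taxon tree, total length 0.1, 100 000 sites, agreement within
three standard errors).

Conventions:

- **Base frequencies** are estimated once from the whole alignment,
  not per pair: stable, matches common package defaults, and keeps the
  matrix consistent across taxon subsets. A composition with a base
  entirely absent is an error (the closed form divides by frequency
  sums); frequency-free models remain available for such data.
- **Missing data** (`-`, `?`, any ambiguity code) is excluded by
  pairwise deletion, which preserves signal in partially gapped rDNA
  alignments; users reconciling with complete-deletion tools should
  expect small differences.
- **Saturation** (a logarithm argument ≤ 0) produces a flagged
  undefined cell, not an exception. Consumers that cannot tolerate
  undefined values — center search, ordering, tree building — refuse
  them with a hard error naming the pair, rather than guessing.

## Tree building

Both builders are written against the same working-matrix contract:
agglomeration ties break at the lowest (row, column) index pair, and a
merged cluster takes the row of its lower-indexed member, so runs are
exactly reproducible. NJ follows Saitou–Nei with the standard
three-point finish, storing the unrooted tree with a trifurcating
root; negative branch lengths (possible on non-additive input) are
kept in memory for diagnostics and clamped to zero only at Newick
output, since parsimony scoring uses the topology alone. UPGMA uses
size-weighted average linkage with node heights at half the merge
distance, so ultrametric input is reproduced exactly. Newick output
orders children by their smallest contained leaf label, making
per-step tree files diffable across runs. Correctness is checked
against a least-squares enumeration oracle over all unrooted
topologies (4–5 taxa), exact recovery of random additive matrices
(up to 8 taxa), and scikit-bio's independent NJ implementation.

## Parsimony scoring

Site scores use Fitch's set method generalised Hartigan-style: at each
internal node, every state's admissibility is counted over the
children; the node keeps the argmax states and pays (children − max
count) changes. At bifurcations this is exactly Fitch
intersection/union; at multifurcations (the NJ root trifurcation) it
remains exact, which plain Fitch does not guarantee. The count is
invariant to rooting for unordered characters. Scoring is vectorised
across sites with 4-bit state masks. Exactness is asserted against
brute-force enumeration of all ancestral assignments on 200 random
instances.

Conventions, chosen where the literature varies:

- Gaps and `?` are missing data (full state set), not a fifth state —
  the dominant practice for rDNA.
- CI is computed over all sites, uninformative ones included; M and S
  count them identically, so this only matters when comparing against
  tools that exclude them (e.g., some PAUP/MEGA outputs).
- S = 0 (invariant or homoplasy-free-trivial sub-alignment) gives
  CI := 1, HI := 0 — required so near-identical taxon sets report "no
  homoplasy" rather than an indeterminate form. Likewise SHI := 0 when
  MaxD = 0.
- RI is reported as NA (never 0) when G = M, i.e., when no site is
  parsimony-informative.
- G is the star-tree Fitch length computed under the same state-set
  semantics as S. With unambiguous bases only this equals the familiar
  "n scored minus the largest state multiplicity"; scoring the star
  tree with sets keeps the invariant M ≤ S ≤ G valid even when
  partial-ambiguity codes (R, Y, …) are present, which the
  unambiguous-only formula does not.

## Downstream analyses

- **CI–distance correlation**: Pearson r between MaxD and CI over the
  steps with CI < 1 (only steps showing homoplasy qualify); NA with
  fewer than three qualifying steps or zero variance.
- **First homoplasy**: the earliest step with HI > 0. "The distance at
  which homoplasy appears" is ambiguous between the added taxon's
  center distance and the subset span, so the step reports both.
- **HI groups**: the center and the three taxa of step 1 share step
  1's HI; each later taxon carries its step's HI; a new group opens
  when HI changes. Because parsimony counts are integers but CI is a
  ratio, equality uses rounding (default 4 decimals, configurable,
  with an exact mode at `decimals=None` semantics via a high decimal
  count). Groups are reported as evidence for species delimitation,
  never as automatic species decisions.

## Synthetic data

The generators emulate exactly the properties the engine claims to
detect, by construction rather than probabilistically:

- **Homoplasy-free mode** assigns each variable site to exactly one
  edge of a random coalescent-style binary tree (derived base below
  the edge). Every variable site fits the generating topology in one
  step, so CI = 1 there is an exact oracle, for every seed.
- **Convergence injection** appends sites whose derived state is
  shared by two disjoint clades whose union is not a bipartition of
  the tree: at least two steps on the true topology, minimum one over
  all trees, hence S grows by exactly 2 and M by exactly 1 per
  injected site. Convergence (not horizontal-transfer-style segment
  swaps) was chosen as the mechanism because it is the simplest
  construction with a provable per-site bound; segment swaps are a
  possible extension.
- **F84 simulation** evolves sites down a tree via the transition
  matrix exponential of the normalised F84 rate matrix, for distance
  recovery checks.

Defaults used in tests and the acceptance script: alignments of a few
hundred sites with roughly a quarter to a third variable sites and
4–12 taxa — the scale of a single rDNA marker across a modest species
panel; branch lengths exponential with mean 0.05 substitutions/site,
giving within-genus scale distances. The generators do not emulate
indels, rate heterogeneity across sites, alignment error, or the
concerted evolution of multi-copy rDNA arrays. Passing tests therefore
show the algorithmic machinery is exact on data satisfying its model
assumptions; they do not certify behaviour on real alignments where
those violations matter.

## Degenerate inputs and edge behaviour

Fewer than four taxa is an error (the first tree needs four). A pair
with zero comparable sites is an error naming the pair. Flank trimming
(removal of leading/trailing columns containing any gap) is offered as
an opt-in convenience and is idempotent; the engine otherwise assumes
pre-trimmed input, and trimming that consumes the whole alignment is
an error. An invariant alignment runs to completion with CI = 1 and
RI = NA throughout.

One caveat demonstrated in the test suite: UPGMA assumes clock-like
distances. On strongly non-ultrametric data it can distort the
topology and report homoplasy that the NJ tree does not — one reason
the two methods are reported side by side.

## Problem sizes

The test suite and the acceptance script use 4–12-taxon alignments of
up to ~400 sites, 100-seed sweeps for the exactness properties, and
100 000 simulated sites for distance recovery; these sizes give exact
or tight stochastic checks while keeping a full run in a few seconds.
The engine itself is O(n³) per step in taxa (NJ) and linear in sites,
comfortable for the tens-of-taxa alignments the method targets.
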