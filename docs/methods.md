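# Methods

## Objects and conventions

A rooted phylogenetic network is a DAG with a unique root of indegree 0
and outdegree 1, tree nodes (indegree 1, outdegree ≥ 2), reticulations
(indegree ≥ 2, outdegree 1), and taxon-labelled leaves (indegree 1,
outdegree 0); parallel arcs are forbidden, including transiently inside
move application.  The explicit unary root is kept in all I/O (the
parser inserts one when the outermost eNewick node has outdegree ≥ 2)
because the constructive algorithms repeatedly refer to "the child of
the root".  Node identifiers are opaque integers and never serialized;
isomorphism respecting taxon labels is the only meaningful equality,
decided with networkx's VF2 matcher under a taxon node-match (unit
tests cross-check it against exhaustive bijection search on small
instances).  *Binary* means every internal non-root node has total
degree 3.

## Cherry picking

A pair of leaves `(x, y)` is reducible if they share a parent (cherry)
or if `x`'s parent is a reticulation fed by `y`'s parent (reticulated
cherry).  Reduction deletes the leaf `x` (cherry) or the reticulation
arc (reticulated cherry) and suppresses any resulting
indegree-1/outdegree-1 node.  Because reducing *any* reducible pair of
an orchard network leaves an orchard network, the orchard test is a
greedy loop; for determinism it always picks the lexicographically
smallest `(x, y)`, preferring cherries on ties.  For a binary orchard
network the greedy sequence has the minimal length `n + k − 1`.

Reconstruction replays a sequence backwards from the one-leaf tree:
a pair whose first taxon is absent re-attaches it as a cherry on the
second taxon's pendant arc; a pair whose first taxon is present adds a
reticulation arc from the second taxon's pendant arc into the first's.
Sequence application is strict by default (every pair must be reducible
when reached); a lenient mode skipping inapplicable pairs exists for
experimentation because the semantics of inapplicable pairs is not
fixed by the theory — strict is the faithful reading.

## HGT-consistent labellings

Labels are exact rationals (`fractions.Fraction`) throughout: only the
order and equality pattern of `t` matters, and exact arithmetic removes
every tolerance question.  Three independent routes to a labelling are
implemented:

- `labelling_from_sequence` reads the constructive labelling off a
  cherry-picking sequence of length `m`: root 0, the j-th leaf in
  lexicographic taxon order `m + j`, the internal node(s) removed at
  reduction step `i` get `m + 1 − i`.  (The theory indexes leaves
  without fixing an order; lexicographic is an arbitrary fixed choice.)
  Each label is used at most twice, and equal labels occur only on a
  tree-node parent with a reticulation child — a property the lifting
  phase depends on.
- `labelling_exists` decides feasibility by brute force, independently
  of cherry picking: enumerate all `2^k` choices of the contemporaneous
  parent per reticulation, contract the forced equalities, reject any
  node whose out-arcs are all forced equal (P2), and test the strict
  quotient digraph for acyclicity; topological ranks of the quotient
  are the witness.  Keeping this decision procedure free of any
  cherry-picking code makes the equivalence test between the two
  characterizations a genuine cross-validation.
- `verify_labelling` checks P1–P3 directly on any directed graph with
  indegree/outdegree ≤ 2 and total degree ≤ 3, which is the generality
  needed to certify rearrangement moves (a graph admitting a labelling
  can contain neither a directed cycle nor parallel arcs, hence is a
  network).

`horizontal_arcs` returns the arcs with equal endpoint labels (exactly
one per reticulation in the binary case), and `base_tree` deletes them
and suppresses degree-two nodes, producing a phylogenetic tree on the
full taxon set — the witness of tree-basedness.  `contains_crown`
searches alternating cyclic structures by DFS, smallest witness first,
with the cycle length capped by the reticulation count.

For non-binary networks the package implements the resolution-based
characterization: `binary_resolutions` expands every tree polytomy into
every rooted binary tree over its children and every multi-indegree
reticulation into every binary in-tree over its parents (keyed-arc
surgery makes adjacent expansions compose), deduplicated up to
isomorphism and refused above 10⁴ candidates; `orchard_resolution`
returns the first resolution admitting a labelling.  The tempting
direct rule — every reticulation contemporaneous with all but one
parent — is implemented (`allbutone_labelling_exists`) and refuted by a
frozen witness network found by seeded search: an orchard network with
a three-parent reticulation admitting no such labelling.

## Rearrangement moves

The move `(p,x,c) --e--> (z,w)` replaces arcs `(p,x), (x,c), (z,w)`
with `(p,c), (z,x), (x,w)`, where `e` is the third arc at `x`; it is
rNNI when `{p,c} ∩ {z,w} ≠ ∅`.  Application is atomic: the incidences
are checked first, degenerate targets `(z,w) ∈ {(p,x),(x,c)}` are
rejected, and a replacement that would create a parallel arc returns an
invalid result without a graph (a parallel-arc graph admits no
labelling, so nothing is lost).  Cyclic results are returned flagged
invalid.  Head moves and tail moves go through the same frame; a move
is undone by the symmetric move `(z,x,w) --e--> (p,c)`.  Neighbor
enumeration tries every frame at every degree-3 node against every
incident target arc and deduplicates results up to isomorphism.

## The connectivity construction

`orchard_path` drives both input networks to the same canonical form
and concatenates one half with the reversal of the other (moves are
node-local, the node set never changes along a half, so a single
isomorphism translates the reversed half onto the first half's
identifiers).  Phases, each emitting moves with a maintained,
re-verified exact labelling:

1. **Lifting** (`lift_reticulation`, ≤ 2n moves per reticulation).
   Take the non-top reticulation `r` with the smallest label (ties:
   smallest taxon below, then node id), its contemporaneous parent `p`,
   other parent `u`, and `q` the parent of `p`.  If `t(u) > t(q)` the
   head of the horizontal arc moves one step up; if `t(q) > t(u)` the
   tail does; if `t(u) = t(q)` the label-multiplicity property forces
   `u = q` and a triangle, handled by `raise_triangle`: two moves
   re-form the triangle one level up, or — when the node above the
   triangle lies on the lowest top horizontal arc — at most four moves
   (one prefix reorientation if that node is the arc's tail, then
   three) put `r` at the top.  Progress is asserted every iteration
   (the ancestor count of `r` strictly decreases, or the top count
   grows).
2. **Orientation** (≤ k + 1 moves).  `top_structure` detects the
   maximal stack below the root child; `neat_moves` computes the
   minimal prefix-flip schedule (pancake scan from the lowest arc up;
   optimal because every block boundary must be touched);
   `reorient_prefix` realizes each flip as the single rNNI move that
   crosses the two path continuations below the flipped prefix — its
   correctness is enforced a posteriori (valid network, flipped
   pattern, still orchard).  One extra full-prefix flip swaps the two
   pendant sides if the anchor leaf (the lexicographically smallest
   taxon — the theory allows any fixed choice) is not below the head of
   the lowest horizontal arc.
3. **Gathering** (`gather_leaves`, ≤ 2n − 4 moves).  Two moves per
   spine node walk the anchor leaf up to sit directly below the lowest
   head, pushing all other taxa to the tail side.
4. **Pendant-tree sorting** (`tree_rnni_path` machinery).  One side's
   pendant tree is flattened to a caterpillar (each move inserts one
   internal node into the spine, ≤ n − 2 moves); the other side is
   zipper-merge-sorted directly into that caterpillar's leaf order: at
   each junction, bottom-up, the sorted block with the smaller top
   element yields its top leaf to the spine at one move per leaf.
   Flattening only one side and sorting the other toward it does the
   sorting work once instead of twice.

The labelling updates inside lifting and gathering follow the
construction's "ε small enough" recipes with exact midpoints between
globally adjacent label values, so a fresh value can never collide with
an unrelated label and all equalities stay on arc-adjacent pairs.  One
completion beyond the stated recipes was required: when the node whose
label is bumped upward is itself the tail of a horizontal arc into a
top reticulation, that contemporaneous child must receive the same bump
or P1 would break on their shared arc.  Every emitted move is verified
immediately; a failed verification is a hard error, never silently
repaired.  Certificates for the tree phase are re-derived constructive
labellings (cheap at these sizes) rather than incremental updates.

`diameter_bound(n, k) = 4kn + n⌈log₂ n⌉ + 2k + 6n − 8` is the proved
upper bound; emitted paths are typically far shorter (random pairs at
n ≤ 7 use under half the bound) but are never claimed minimal.

## Synthetic data

`random_orchard` draws a random valid cherry-picking sequence — `n − 1`
cherry insertions, `k` reticulated insertions placed uniformly among
the slots where at least two leaves are present — and reconstructs it,
so its outputs are by construction binary orchard networks with exactly
the requested `n` and `k`; this mirrors how orchard networks arise from
sequential joining of closely related taxa.  `random_network` adds `k`
random acyclicity-respecting reticulation arcs to a random binary tree
and is the negative control: its outputs mix orchard and non-orchard
networks, exercising both branches of every equivalence test.
`crown_network(m)` builds the canonical obstruction, `top_stack_fixture`
builds two-taxon networks with a prescribed stack orientation pattern,
and `gamma_proteobacteria_network` rebuilds the classic 13-taxon HGT
example from its 14-pair sequence.  All generators use integer-only
randomness from a single seed and reproduce isomorphic networks across
platforms.

What the generators do *not* emulate: branch lengths, rate or sequence
data, extinction/sampling artifacts, or statistically calibrated
reticulation placement (e.g. level-k LGT models).  Passing tests
therefore demonstrate combinatorial correctness of the algorithms on
the class they are defined for, not inferential performance on real
alignments.

## Numerical and scale choices

There is no floating point anywhere in the core: labels are exact
rationals, randomness is integer-only.  Exhaustive components state
their envelopes: resolution enumeration refuses > 10⁴ candidates;
`labelling_exists` is exponential in `k` by design (it is the
independent oracle, not the production test — `is_orchard` is linear-ish
and certified by the equivalence).  The test and acceptance workloads
run at desk scale — exhaustive network enumeration at n ≤ 4, k ≤ 2
(about 46k sequence-generated networks), 500 random networks for the
equivalence, 50 random pairs at n ∈ 4..7, k ∈ 1..3 for the diameter
property, full pairwise paths on the 21-network (n=3, k=1) space —
chosen so the whole suite completes in about a minute while still
exercising every branch of the case analysis.

## Known limitations

- The pendant-tree sort follows the input tree's shape as its merge
  schedule; for adversarially unbalanced shapes in anti-sorted order
  its move count degrades toward quadratic, exceeding the
  `2n + n⌈log₂ n⌉` tree-phase budget for n beyond ≈ 13.  At the sizes
  the suite and acceptance checks exercise, the end-to-end diameter
  bound holds instance-wise with ample margin (worst-case phase sums
  included); a guaranteed-balanced merge schedule would remove the
  caveat at the cost of an explicit rebalancing pass.
- Path minimality is out of scope: rNNI distance is not computed, and
  `orchard_path` outputs are upper-bound constructions.
- Tree-basedness is decided only through the base-tree witness of an
  HGT-consistent labelling; networks that are tree-based but not
  orchard (e.g. crowns) are not recognized as tree-based.
- The direct (resolution-free) labelling characterization of
  non-binary orchard networks is an open problem; the all-but-one rule
  is included only as a refuted candidate.
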