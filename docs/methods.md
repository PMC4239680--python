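# Methods

## The model

A genome is a *gene order*: a string of signed symbols over an alphabet of
gene families. Repeated symbols are paralogs; the sign is transcriptional
orientation. Evolution acts through three operations, each with a length
`k` (in genes), a *source* (the substring the event reads) and a *target*
(the substring it writes):

* duplication `D(k)` — copy the source to a new location outside itself.
  A duplication whose source lies in a different genome doubles as a
  transposition or transfer surrogate, which is why no explicit
  transposition operation is needed;
* loss `L(k)` — delete the source (empty target);
* reversal `R(k)` — replace the source in place by its reverse: order
  flipped, every sign negated.

A branch history is an ordered event sequence turning an ancestor into a
descendant; its cost is the sum of per-event costs under a `CostScheme`.
Two schemes ship with the package: `unit` (one per event, any length) and
`dup_singleloss` (unit duplications, per-gene losses — the restricted
model used for all accuracy experiments, under which cost equals event
count when losses are single genes).

For closely related genomes, events can be assumed non-overlapping (each
gene participates in at most one event), so a history remains *visible* in
an alignment of the genomes involved. This motivates the central object,
the **labeled alignment**: a gap-padded alignment together with a set of
operations such that, for every row pair and column, a match is covered by
no operation, a mismatch by exactly one reversal, and a gap by exactly one
other operation; operations between related rows flow away from the
ancestor. A labeled alignment corresponds to a realizable history only
when it is **feasible**: its operations admit no cycle, i.e. no circular
chain in which each duplication's target overlaps the next one's source.
Only duplications with both source and target in observed (non-ancestral)
genomes can participate in such a cycle — a loss has no target, and a
reversal in a cycle would force a doubly covered column.

## The 3-star heuristic

The directed median problem: given a grandparent assignment `A` above a
cherry `X, Y`, choose the center `M` and histories `A->M`, `M->X`, `M->Y`
of minimum total cost. Duplications and losses are asymmetric in time, so
the direction of evolution cannot be dropped — this is a *directed*
median, not a distance median.

The solver reduces the problem to finding a cheap feasible labeled
alignment of `{A, X, Y}` and proceeds in two steps.

**Step 1 — dynamic programming.** `C(i, j, k)` is the cheapest labeled
alignment of the prefixes `A[:i]`, `X[:j]`, `Y[:k]`, filled by
interpreting the last column block in every admissible way: an all-match
column; a reversal above the center (`X` and `Y` share a suffix that is
the reverse of `A`'s) or on one child branch; a duplication above the
center (`X` and `Y` share a suffix occurring in `A`) or private to one
child (suffix occurring anywhere visible, excluding the exact target
position); a loss on one child branch (suffix shared by `A` and the
surviving child), in both children (any suffix of `A`, charged once), and
the two compound column shapes (reversal above the center plus a loss in
one child; duplication above the center plus a reversal in one child). A
column needing two events is interpreted with both events of equal length;
a column with three distinct symbols is inadmissible. Extension sets
collect *all* valid suffix lengths, capped by the relevant prefix lengths.
Work is bounded by a constant times `|A|·|X|·|Y|·max-extension`, i.e.
O(n^4) in the worst case.

Cells carry a secondary objective alongside the cost: the number of genes
covered by child-private duplications. Among equal-cost interpretations
the backtracking therefore prefers labelings with fewer leaf-internal
duplications — the only operations that can later form cycles — and then
a fixed case priority (match, losses, shared duplication, reversals,
private duplications, compound cases) with longer extensions first. This
keeps backtracking deterministic and the center close to `A`.

Duplication sources are chosen after backtracking: an occurrence in `A`
if one exists, otherwise an occurrence disjoint from every duplication
target, otherwise whatever remains. The recurrences only require *some*
visible occurrence, so this choice is free, and taking cycle-safe sources
removes most infeasibility before the repair step has to pay for it.

**Step 2 — cycle repair.** The overlap graph has the leaf-internal
duplications as nodes and an edge wherever one operation's target interval
intersects another's source interval in the same genome (interval
intersection is used as the overlap test: any overlap means the second
event copied genes that exist only once the first has happened). Every
non-trivial strongly connected component yields a reported cycle, and a
runtime assertion checks that cycle members are all duplications. Repair
is greedy, smallest cycle first: among the cycle's target strings, pick
the one with the minimum-cardinality decomposition into substrings of `A`
(shortest path over cut positions; leftmost-longest reconstruction); that
target is relabeled as one loss in the sibling plus one duplication from
`A` per part. Each repair removes a leaf-sourced duplication and adds
none, so the loop terminates. When no cycle member decomposes over `A`
(possible only when a family of `X`/`Y` never occurs in `A`), a per-gene
fallback sources each gene from `A` if possible, then from the other
leaf, then from elsewhere in the same leaf.

**Extraction.** From the feasible labeling the center is read per column
(shared symbol on matches; the surviving child's symbol under branch
losses and reversals; the duplicated content under center duplications;
absent under center losses and private duplications), and the three
histories are materialized right-to-left so that each event's coordinates
are valid in the intermediate genome at its application time; all three
replays are verified.

Finally the three branch costs are recomputed around the extracted center
with the directed pairwise aligner, and the cheaper decomposition is
kept. The pairwise view can merge events that the column-block
recurrences had to split — typically a center duplication whose image in
one child was split by that child's own insertion — and the summed
pairwise costs correspond to a genuine history, so the reported cost is
always realizable. The method remains a heuristic with no optimality
guarantee.

## Pairwise alignment

Cherry (sibling) and directed (ancestor-descendant) alignment use the
two-row restriction of the same case semantics. In sibling mode the
parent is free: a gap column is a loss in the gapped child (parent keeps
the segment) or a duplication in the other child; ties prefer the loss,
keeping the parent maximal — the same direction the cycle repair takes.
In directed mode every operation flows from the ancestor: gaps in the
descendant are losses, gaps in the ancestor are duplications with a
visible source, mismatched blocks are reversals. The inferred parent of a
cherry is read off the labeling column by column, and branch histories
are materialized and replay-verified exactly as in the 3-star case.

## Steinerization

The tree driver initializes every internal node bottom-up as the inferred
parent of its children's cherry alignment, then sweeps internal nodes in
post-order, re-solving the local 3-star around each node (parent above,
children below) and accepting the new center only when the three incident
branch costs strictly decrease. Replacements take effect immediately
within the sweep, so the total tree cost — the sum of directed branch
costs over all edges — is non-increasing by construction, and strict
improvement guarantees termination; runs converge well before the default
cap of 20 rounds. The root, which has no grandparent, is re-optimized as
the free parent of its two children; children of the root use the root's
assignment as their `A`. Branch costs are always recomputed by the
directed aligner (memoized by genome content) rather than trusted from
the 3-star solution. Non-binary trees are rejected.

A multiple alignment over all nodes is assembled by threading each branch
alignment and each child subtree's alignment along their shared row. In
the merged view an operation's column interval may span columns where its
own rows are all gaps (insertions contributed by other subtrees); the
per-branch labeling is to be read on non-gap cells, and inducing the
alignment onto one parent-child pair recovers that branch's labeling.

## The simulator

The generator reproduces the benchmark protocol: a uniform random root
sequence of length `n` over `sigma` families receives `l` moves, and
every other genome receives `l` moves from its direct ancestor, down a
given topology, a random binary topology (sequential random cherry
attachment), or the triplet used for 3-star benchmarking (`A` above the
true center, children `X` and `Y`). Duplication lengths are geometric
with parameter 0.5 (support k >= 1, mean 2); sources start uniformly at
random and the copy is inserted at a uniform position outside the source.
The `dup_singleloss` model (unsigned genomes, single-gene losses) is the
one used in all accuracy comparisons; `dup_loss_reversal` adds
geometric-length reversals and losses for signed data. The
duplication/loss mixture is not fixed by the protocol; the generator uses
an even split by default and records it. A loss that would empty the
genome is resampled. Every branch's true history is retained and replay
of it reproduces the child exactly — this is asserted, not assumed.

What the generator does *not* emulate: rate heterogeneity across
branches or sites, gene-family birth by insertion or transfer from
outside the tree, orientation bias, multi-chromosomal structure, or any
clustering of events along the genome. Passing tests on these synthetic
data therefore demonstrate correctness of the algorithms under the
declared model, not performance on real gene orders whose histories
violate the visibility assumption.

## The exact oracle

Validation needs an independent optimum. The enumerator searches visible
histories directly through their one-to-one correspondence with feasible
labeled alignments: columns are generated left to right; open loss runs
and duplication targets are carried as search state; a duplication part
may only grow while its content occurs somewhere disjoint from the part's
own target image (an event cannot source the genes it creates); loss and
duplication events group by contiguity in the genome they act on, so a
single event may span columns interleaved with other rows' insertions.
Iterative deepening on total cost with memoized states returns the
optimum; candidate labelings whose duplication sources cannot be arranged
acyclically are rejected and the search continues, with a lenient
re-enumeration pass reserved for the rare case that every witness at a
level is cyclic. The 3-star oracle covers the duplication + loss model on
unsigned genomes; the pair oracle additionally handles reversal blocks.
Duplication costs must be length-independent and loss costs
non-decreasing; both shipped schemes qualify. The oracle refuses
instances beyond its explicit budget (genome length, cost ceiling, node
ceiling) rather than degrading silently, and is a validation tool, not a
production path.

The oracle's minimum-partition logic is greedy leftmost-longest, optimal
here because substrings of a genome form a factor-closed set; the
package's own `min_decomposition` uses a shortest-path formulation, and
the two agreeing on random inputs is used as a cross-check in the tests.

## Experiment sizes and defaults

The accuracy experiment mirrors the published ratios `sigma/n = 1/2` and
`l/n = 1/20` at the smallest size with one whole move per branch:
`n = 20`, `sigma = 10`, `l = 1`, duplication + single-gene-loss model, 50
replicates — a size at which the exhaustive solver is practical on one
CPU in minutes. Per-replicate seeds derive deterministically from one
experiment seed. Steinerization properties run on 20 seeded trees of 5-8
leaves at `n = 12-20`; heuristic-versus-oracle property suites use `n = 5`,
`sigma = 3` triplets where exhaustive search is instant. These sizes are
the package's validation choices; all entry points accept larger values.

Other defaults worth knowing: unit costs (the general default) versus
`dup_singleloss` (experiments); `max_rounds = 20` for steinerization;
oracle budget of 40 genes per genome, 110 total, cost ceiling 16, 6M
search nodes. Numerical comparisons use an absolute tolerance of 1e-9 on
costs; the DP's unreachable sentinel is a finite value strictly above any
achievable labeling cost, never a floating-point infinity.

## Known limitations

* The 3-star and pairwise solvers are heuristics; the per-column "at most
  two same-length events" rule and contiguous extension blocks mean some
  optima (notably events whose images are split by later insertions) are
  found only via the post-extraction pairwise recomputation, and others
  not at all.
* Cycle repair follows the greedy printed rule per cycle; jointly optimal
  repair across cycles is out of scope.
* Reversal support in the exact oracle is pairwise-only; 3-star instances
  with signed content are validated by replay and feasibility, not by
  optimality comparison.
* Unsigned data is represented with all-positive signs and compared
  sign-exactly, so reversal cases never fire on it by construction.
* The steinerization explores assignments only; tree topology search,
  branch lengths and multifurcations are out of scope.
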