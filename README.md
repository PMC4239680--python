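# orderalign

Ancestral gene-order reconstruction on phylogenies under a
duplication–loss–reversal model.

Given present-day genomes represented as *gene orders* — strings of signed
gene-family symbols, with paralogs as repeated symbols — and a rooted binary
species tree, `orderalign` infers a gene order for every internal node by
relating gene-order comparison to an alignment problem. It is aimed at
closely related genomes (for example bacterial stable-RNA gene repertoires)
where few events separate neighbouring nodes, so each event is still
*visible* in an alignment: every gene takes part in at most one event.

## The problem and the method

Evolution acts on a gene order through duplications `D(k)` (copy a
substring of `k` genes elsewhere; a cross-genome source doubles as a
transposition surrogate), losses `L(k)` (delete a substring) and reversals
`R(k)` (flip a substring's order and signs). A *labeled alignment* of two
or more genomes pairs a gap-padded alignment with a set of operations that
explains every non-match column — matches covered by nothing, mismatches by
exactly one reversal, gaps by exactly one other operation — and it is
*feasible* when no circular chain of duplications sources genes from each
other's targets. Feasible labeled alignments correspond one-to-one to
visible histories, so minimizing event cost over them infers ancestors.

The package's core is a dynamic-programming heuristic for the **3-star
problem**: given a grandparent assignment `A` above a cherry `X, Y`, find
the center `M` and branch histories `A→M`, `M→X`, `M→Y` of minimum total
cost,

    C(A→M) + C(M→X) + C(M→Y),

a *directed* median — duplications and losses are asymmetric in time, so
direction cannot be ignored. A cubic table `C(i, j, k)` over prefix lengths
is filled by interpreting the last alignment column in all admissible ways
(nine case families), backtracking yields a labeled alignment, cycles are
repaired by relabeling a duplication target as a sibling loss plus
duplications from `A`, and the center with its three histories is read off
the feasible labeling. The **small phylogeny** driver assigns all internal
nodes by *steinerization*: initialize each node as the inferred parent of
its children's cherry alignment, then sweep the tree re-solving local
3-stars until the total tree cost stops decreasing. A simulator with
ground-truth histories and an exhaustive exact solver for tiny instances
round out the package for validation. See `docs/methods.md` for the full
account.

## Worked example

Three genomes over families `a..e`, with `A` ancestral to the cherry
`X, Y` (one symbol per gene; a leading `-` would mark negative
orientation):

```sh
$ printf 'A\ta b c d e\nX\ta c d e a b d e a b d e\nY\ta c d e\n' > genomes.tsv
$ orderalign median --genomes genomes.tsv --ancestor A --left X --right Y
cost	5
center	a c d e a b d e
```

The inferred center lost `b` relative to `A` and gained one `abde` repeat;
under unit costs the heuristic explains the triple with 5 events (the
exhaustive oracle, `orderalign oracle`, certifies 4 as the optimum on this
deliberately repetitive instance — the heuristic trades optimality for
polynomial time). The same machinery on a tree:

```sh
$ printf 'a\tg1 g2 g3 g4\nb\tg1 g3 g4\nc\tg1 g2 g3 g4 g2 g3\n' > leaves.tsv
$ printf '((a,b),c);\n' > tree.nwk
$ orderalign tree --tree tree.nwk --genomes leaves.tsv --out-dir out
final_cost	2
rounds	1
$ cat out/assignments.tsv
id	genes
N1	g1 g2 g3 g4 g2 g3
N2	g1 g2 g3 g4
a	g1 g2 g3 g4
b	g1 g3 g4
c	g1 g2 g3 g4 g2 g3
```

The two events are the loss of `g2` on the branch to `b` and the tandem
`g2 g3` duplication placed on the branch into the root's child — the root
`N1` keeps the repeat because the cherry alignment's tie-break prefers the
loss reading, and one re-optimization round confirms the assignment is a
local minimum (`out/rounds.tsv` logs the non-increasing per-round cost).

From Python:

```python
from orderalign import StarInstance, GeneOrder, solve_star

inst = StarInstance(GeneOrder.from_string("abcde"),
                    GeneOrder.from_string("acdeabdeabde"),
                    GeneOrder.from_string("acde"))
sol = solve_star(inst)
print(sol.cost)                  # 5.0
print(str(sol.center))           # a c d e a b d e
```

Subcommands: `align-pair` (cherry or directed branch alignment), `median`
(one 3-star), `tree` (full steinerization), `simulate` (synthetic genomes
with ground truth), `oracle` (exhaustive exact cost for tiny instances).

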