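"""Synthetic gene-order evolution with ground-truth histories.

The generator follows the triplet/tree protocol used to benchmark the
aligner: a random root sequence of length ``n`` over ``sigma`` gene families
receives ``l`` moves, and every other genome along the (given or random
binary) tree is produced by applying ``l`` moves to its direct ancestor.
Duplication lengths follow a geometric distribution with parameter 0.5
(support k >= 1, mean 2); duplication sources start uniformly at random and
the copy is inserted at a uniform position outside the source interval.

Two event models are provided: ``dup_singleloss`` (unsigned genomes,
duplications plus single-gene losses — the model used for the accuracy
comparisons) and ``dup_loss_reversal`` (signed genomes; losses and reversals
also take geometric lengths).  The duplication/loss mixture is an even split
by default; it is a free parameter of the protocol, not a fitted value.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .model import (DUP, LOSS, REV, CostScheme, Gene, GeneOrder, History,
                    Operation, StarInstance, replay_history)
from .tree import AssignedTree, TreeNode

MODELS = ("dup_singleloss", "dup_loss_reversal")


@dataclass(frozen=True)
class SimulationParams:
    """Protocol parameters: root length n, alphabet size sigma, moves per
    branch l, event model, geometric length parameter, duplication share."""

    n: int = 100
    sigma: int = 50
    l: int = 5
    model: str = "dup_singleloss"
    dup_length_p: float = 0.5
    p_dup: float = 0.5  # probability that a move is a duplication
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0 or self.sigma < 0 or self.l < 0:
            raise ValueError("n, sigma, l must be non-negative")
        if not (0 < self.dup_length_p <= 1):
            raise ValueError("dup_length_p must be in (0, 1]")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SimulatedInstance:
    """A fully assigned tree plus the true per-branch histories."""

    tree: AssignedTree
    histories: dict[str, History]  # child node id -> history parent->child
    params: SimulationParams

    @property
    def true_counts(self) -> dict[str, int]:
        return {k: len(h) for k, h in self.histories.items()}

    @property
    def total_true_events(self) -> int:
        return sum(self.true_counts.values())


def random_genome(n: int, sigma: int, rng: random.Random, id: str = "R") -> GeneOrder:
    """Uniform random sequence of n genes over sigma families, all forward."""
    if n > 0 and sigma < 1:
        raise ValueError("need at least one family for a non-empty genome")
    return GeneOrder(tuple(Gene(f"g{rng.randrange(sigma)}") for _ in range(n)), id)


def geometric(p: float, rng: random.Random) -> int:
    """Geometric length with support k >= 1: P(k) = p (1-p)^(k-1)."""
    k = 1
    while rng.random() >= p:
        k += 1
    return k


def apply_moves(genome: GeneOrder, l: int, params: SimulationParams,
                rng: random.Random, id: str = "") -> tuple[GeneOrder, History]:
    """Apply l random events to a genome, recording the true history."""
    if l > 0 and len(genome) == 0:
        raise ValueError("cannot evolve an empty genome")
    gid = id or genome.id
    current = genome.with_id(gid)
    history: History = []
    for _ in range(l):
        op = _sample_move(current, params, rng)
        current = replay_history(current, [op])
        history.append(op)
    return current, history


def _sample_move(current: GeneOrder, params: SimulationParams,
                 rng: random.Random) -> Operation:
    n = len(current)
    gid = current.id
    r = rng.random()
    if params.model == "dup_singleloss":
        kind = DUP if r < params.p_dup or n <= 1 else LOSS
    else:
        third = (1.0 - params.p_dup) / 2.0
        if r < params.p_dup or n <= 1:
            kind = DUP
        elif r < params.p_dup + third:
            kind = LOSS
        else:
            kind = REV
    if kind == DUP:
        k = min(geometric(params.dup_length_p, rng), n)
        s1 = rng.randrange(n - k + 1)
        # insertion point outside the copied interval: before its start or
        # after its end
        positions = list(range(0, s1 + 1)) + list(range(s1 + k, n + 1))
        t = rng.choice(positions)
        return Operation(DUP, k, source=(gid, (s1, s1 + k)),
                         target=(gid, (t, t + k)),
                         content=tuple(current.genes[s1:s1 + k]))
    if kind == LOSS:
        # a loss never empties the genome (resampled length / position)
        k = 1 if params.model == "dup_singleloss" else \
            min(geometric(params.dup_length_p, rng), n - 1)
        s1 = rng.randrange(n - k + 1)
        return Operation(LOSS, k, source=(gid, (s1, s1 + k)))
    k = min(geometric(params.dup_length_p, rng), n)
    s1 = rng.randrange(n - k + 1)
    return Operation(REV, k, source=(gid, (s1, s1 + k)),
                     target=(gid, (s1, s1 + k)))


def random_topology(n_leaves: int, rng: random.Random) -> AssignedTree:
    """Random rooted binary topology by sequential random cherry attachment."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    counter = [0]

    def inner() -> TreeNode:
        counter[0] += 1
        return TreeNode(f"N{counter[0]}")

    leaves = [TreeNode(f"L{i + 1}") for i in range(n_leaves)]
    pool = list(leaves)
    while len(pool) > 1:
        i = rng.randrange(len(pool))
        a = pool.pop(i)
        j = rng.randrange(len(pool))
        b = pool.pop(j)
        parent = inner()
        parent.children = [a, b]
        pool.append(parent)
    return AssignedTree(pool[0])


def simulate_tree(topology, params: SimulationParams,
                  rng: random.Random | None = None) -> SimulatedInstance:
    """Evolve genomes down a tree: the root receives l moves on a fresh
    random sequence, every child receives l moves on its parent's genome."""
    rng = rng or random.Random(params.seed)
    if isinstance(topology, int):
        tree = random_topology(topology, rng)
    else:
        tree = topology
    seq = random_genome(params.n, params.sigma, rng, id="R")
    root_genome, _ = apply_moves(seq, params.l, params, rng, id=tree.root.id)
    tree.root.genome = root_genome
    histories: dict[str, History] = {}
    for node in tree.nodes.values():  # insertion order: parent before child
        for child in node.children:
            child.genome, hist = apply_moves(node.genome, params.l, params,
                                             rng, id=child.id)
            histories[child.id] = hist
    return SimulatedInstance(tree=tree, histories=histories, params=params)


def simulate_star(params: SimulationParams,
                  rng: random.Random | None = None) -> tuple[StarInstance, dict[str, History]]:
    """A 3-star instance with known truth: A above the true center M, with
    children X and Y, each branch carrying exactly l moves."""
    rng = rng or random.Random(params.seed)
    seq = random_genome(params.n, params.sigma, rng, id="A")
    A, _ = apply_moves(seq, params.l, params, rng, id="A")
    M, h_m = apply_moves(A, params.l, params, rng, id="M")
    X, h_x = apply_moves(M, params.l, params, rng, id="X")
    Y, h_y = apply_moves(M, params.l, params, rng, id="Y")
    costs = (CostScheme.dup_singleloss() if params.model == "dup_singleloss"
             else CostScheme.unit())
    return (StarInstance(A, X, Y, costs),
            {"M": h_m, "X": h_x, "Y": h_y})


def evaluation_metrics(inf: float, opt: float, nb_opt: int | None = None,
                       total: int | None = None) -> tuple[float, float | None]:
    """Error = (Inf - Opt) / Inf;  Accuracy = NbOpt / Total.

    ``Inf`` is the event count inferred by the heuristic and ``Opt`` the
    reference optimal count; ``NbOpt`` of ``Total`` simulations agreed
    exactly.  Accuracy is None when the counts are not supplied.
    """
    if inf == 0:
        if opt != 0:
            raise ValueError("zero inferred events with non-zero optimum")
        error = 0.0
    else:
        error = (inf - opt) / inf
    accuracy = None
    if total is not None:
        if total <= 0:
            raise ValueError("total must be positive")
        accuracy = nb_opt / total
    return error, accuracy
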