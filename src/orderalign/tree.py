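"""Phylogenetic alignment by steinerization.

Given a rooted binary species tree with a gene order at every leaf, the
driver (1) initializes every internal node bottom-up as the inferred parent
of its children's cherry alignment, then (2) sweeps the internal nodes in
post-order, re-solving the local 3-star ``A|XY`` around each node (its
parent's assignment above, its children's below) and keeping the new center
only when the three incident branch costs strictly improve, and (3) repeats
until a sweep makes no change.  The total tree cost — the sum of directed
branch alignment costs — is non-increasing across rounds by construction.

The root has no grandparent, so it is re-optimized as the free parent of its
two children (the two-species small-phylogeny view); children of the root
use the root's assignment as the A of their 3-stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .median import solve_star
from .model import CostScheme, GeneOrder, LabeledAlignment, StarInstance
from .pairwise import align_directed, align_siblings


@dataclass
class TreeNode:
    id: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    genome: Optional[GeneOrder] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class AssignedTree:
    """A rooted binary tree whose nodes carry gene-order assignments."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        for node in self._walk(root):
            if node.id in self.nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
            for ch in node.children:
                ch.parent = node
        for node in self.nodes.values():
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"non-binary node {node.id!r} with {len(node.children)} "
                    "children; resolve multifurcations before running")

    @staticmethod
    def _walk(node: TreeNode) -> Iterator[TreeNode]:
        yield node
        for ch in node.children:
            yield from AssignedTree._walk(ch)

    def postorder(self) -> Iterator[TreeNode]:
        def rec(n: TreeNode) -> Iterator[TreeNode]:
            for ch in n.children:
                yield from rec(ch)
            yield n
        return rec(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        return [(n.parent, n) for n in self.postorder() if n.parent is not None]

    @classmethod
    def from_parent_map(cls, children: dict[str, tuple[str, str]],
                        root_id: str) -> "AssignedTree":
        built: dict[str, TreeNode] = {}

        def make(nid: str) -> TreeNode:
            if nid in built:
                return built[nid]
            node = TreeNode(nid)
            built[nid] = node
            if nid in children:
                node.children = [make(c) for c in children[nid]]
            return node

        return cls(make(root_id))


@dataclass
class RoundLog:
    """Per-round total cost and number of replaced assignments."""

    entries: list[tuple[int, float, int]] = field(default_factory=list)

    def record(self, rnd: int, cost: float, improved: int) -> None:
        self.entries.append((rnd, cost, improved))

    @property
    def costs(self) -> list[float]:
        return [c for _, c, _ in self.entries]

    @property
    def rounds(self) -> int:
        return len(self.entries) - 1  # entry 0 is the initialization


class BranchCostCache:
    """Memoizes directed branch costs by genome content."""

    def __init__(self, costs: CostScheme):
        self.costs = costs
        self._cache: dict[tuple, float] = {}

    def cost(self, anc: GeneOrder, desc: GeneOrder) -> float:
        key = (anc.genes, desc.genes)
        if key not in self._cache:
            self._cache[key] = align_directed(anc, desc, self.costs).cost
        return self._cache[key]


def initialize_assignments(tree: AssignedTree, costs: Optional[CostScheme] = None,
                           method: str = "pairwise") -> AssignedTree:
    """Bottom-up initialization: each internal node becomes the inferred
    parent of the cherry alignment of its two children's assignments."""
    if method != "pairwise":
        raise ValueError(f"unknown initialization method {method!r}")
    costs = costs or CostScheme.unit()
    for leaf in tree.leaves():
        if leaf.genome is None:
            raise ValueError(f"leaf {leaf.id!r} has no genome assigned")
    for node in tree.postorder():
        if node.is_leaf:
            continue
        left, right = node.children
        res = align_siblings(left.genome, right.genome, costs)
        node.genome = res.inferred_parent.with_id(node.id)
    return tree


def tree_cost(tree: AssignedTree, costs: Optional[CostScheme] = None,
              cache: Optional[BranchCostCache] = None) -> float:
    """Sum of directed branch costs over all edges of the assigned tree."""
    costs = costs or CostScheme.unit()
    cache = cache or BranchCostCache(costs)
    total = 0.0
    for parent, child in tree.edges():
        if parent.genome is None or child.genome is None:
            raise ValueError(f"unassigned node on edge {parent.id}->{child.id}")
        total += cache.cost(parent.genome, child.genome)
    return total


def reoptimize_round(tree: AssignedTree, costs: Optional[CostScheme] = None,
                     cache: Optional[BranchCostCache] = None) -> tuple[AssignedTree, bool]:
    """One post-order sweep of local 3-star re-optimization.

    Each internal node is revisited against the current assignments of its
    parent and children (the sweep order is fixed up front); a replacement is
    kept only when the summed cost of the three incident branches strictly
    decreases, which guarantees the total tree cost never increases.
    """
    costs = costs or CostScheme.unit()
    cache = cache or BranchCostCache(costs)
    improved = 0
    eps = 1e-9
    for node in list(tree.postorder()):
        if node.is_leaf:
            continue
        left, right = node.children
        if node.parent is not None:
            anc = node.parent.genome
            inst = StarInstance(anc, left.genome, right.genome, costs)
            sol = solve_star(inst)
            cand = sol.center.with_id(node.id)
            old = (cache.cost(anc, node.genome)
                   + cache.cost(node.genome, left.genome)
                   + cache.cost(node.genome, right.genome))
            new = (cache.cost(anc, cand)
                   + cache.cost(cand, left.genome)
                   + cache.cost(cand, right.genome))
        else:  # root: free parent of its two children
            res = align_siblings(left.genome, right.genome, costs)
            cand = res.inferred_parent.with_id(node.id)
            old = (cache.cost(node.genome, left.genome)
                   + cache.cost(node.genome, right.genome))
            new = (cache.cost(cand, left.genome)
                   + cache.cost(cand, right.genome))
        if new < old - eps:
            node.genome = cand
            improved += 1
    return tree, improved > 0


def run_steinerization(tree: AssignedTree, costs: Optional[CostScheme] = None,
                       max_rounds: int = 20) -> tuple[AssignedTree, RoundLog]:
    """Initialize, then re-optimize until a sweep makes no replacement."""
    costs = costs or CostScheme.unit()
    cache = BranchCostCache(costs)
    initialize_assignments(tree, costs)
    log = RoundLog()
    log.record(0, tree_cost(tree, costs, cache), 0)
    for rnd in range(1, max_rounds + 1):
        tree, improved = reoptimize_round(tree, costs, cache)
        cost = tree_cost(tree, costs, cache)
        if cost > log.costs[-1] + 1e-9:  # pragma: no cover - contract guard
            raise AssertionError("tree cost increased during re-optimization")
        log.record(rnd, cost, int(improved))
        if not improved:
            break
    return tree, log


def build_multiple_alignment(tree: AssignedTree) -> LabeledAlignment:
    """Merge branch alignments bottom-up into one multiple alignment.

    Rows are all tree nodes (internal assignments included).  Labeling
    operations are carried over per branch with their column intervals
    remapped; in the merged view an interval may span columns where the
    branch's own rows are all gaps (insertions contributed by other
    subtrees), so the per-branch labeling is to be read on non-gap cells —
    inducing the alignment onto one parent/child pair recovers that branch's
    feasible labeled alignment.
    """
    costs = CostScheme.unit()

    def rec(node: TreeNode) -> LabeledAlignment:
        if node.genome is None:
            raise ValueError(f"unassigned node {node.id!r}")
        if node.is_leaf:
            return LabeledAlignment(rows={node.id: tuple(node.genome.genes)},
                                    row_order=[node.id], ops=[])
        acc = LabeledAlignment(rows={node.id: tuple(node.genome.genes)},
                               row_order=[node.id], ops=[])
        for child in node.children:
            res = align_directed(node.genome, child.genome, costs)
            branch = _rename_rows(res.alignment, {"A": node.id, "X": child.id})
            sub = rec(child)
            branch_plus = _merge(branch, sub, shared=child.id)
            acc = _merge(acc, branch_plus, shared=node.id)
        return acc

    return rec(tree.root)


def _rename_rows(aln: LabeledAlignment, mapping: dict[str, str]) -> LabeledAlignment:
    from .model import AlignOp
    rows = {mapping.get(k, k): v for k, v in aln.rows.items()}
    order = [mapping.get(k, k) for k in aln.row_order]
    ops = []
    for op in aln.ops:
        covers = frozenset(frozenset(mapping.get(r, r) for r in pair)
                           for pair in op.covers)
        src = op.source
        if src is not None and src[0] in mapping:
            src = (mapping[src[0]], src[1])
        ops.append(AlignOp(op.kind, op.cols, mapping.get(op.branch, op.branch),
                           covers, src))
    anc = frozenset(mapping.get(r, r) for r in aln.ancestors)
    return LabeledAlignment(rows=rows, row_order=order, ops=ops, ancestors=anc)


def _merge(a1: LabeledAlignment, a2: LabeledAlignment, shared: str) -> LabeledAlignment:
    """Thread two alignments along a common row (equal ungapped content)."""
    from .model import AlignOp
    s1, s2 = a1.rows[shared], a2.rows[shared]
    assert tuple(g for g in s1 if g is not None) == \
        tuple(g for g in s2 if g is not None), "shared rows disagree"
    map1: dict[int, int] = {}
    map2: dict[int, int] = {}
    cols: list[tuple[Optional[int], Optional[int]]] = []
    i1 = i2 = 0
    n1, n2 = len(s1), len(s2)
    while i1 < n1 or i2 < n2:
        if i1 < n1 and s1[i1] is None:
            map1[i1] = len(cols)
            cols.append((i1, None))
            i1 += 1
        elif i2 < n2 and s2[i2] is None:
            map2[i2] = len(cols)
            cols.append((None, i2))
            i2 += 1
        else:  # both sit on the same shared gene
            map1[i1] = map2[i2] = len(cols)
            cols.append((i1, i2))
            i1 += 1
            i2 += 1
    rows: dict[str, tuple] = {}
    order: list[str] = []
    for rid in a1.row_order + [r for r in a2.row_order if r != shared]:
        order.append(rid)
        src_rows, mapping = (a1.rows, 0) if rid in a1.rows else (a2.rows, 1)
        rows[rid] = tuple(
            src_rows[rid][c[mapping]] if c[mapping] is not None else None
            for c in cols)
    ops: list[AlignOp] = []
    for op in a1.ops:
        ops.append(AlignOp(op.kind, (map1[op.cols[0]], map1[op.cols[1] - 1] + 1),
                           op.branch, op.covers, op.source))
    for op in a2.ops:
        ops.append(AlignOp(op.kind, (map2[op.cols[0]], map2[op.cols[1] - 1] + 1),
                           op.branch, op.covers, op.source))
    return LabeledAlignment(rows=rows, row_order=order, ops=ops,
                            ancestors=a1.ancestors | a2.ancestors)
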