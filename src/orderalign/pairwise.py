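"""Pairwise labeled alignment: cherries and ancestor->descendant branches.

Two modes share one small dynamic program, the two-row restriction of the
3-star case set:

* **sibling mode** aligns the two children ``X, Y`` of a cherry.  The parent
  is free, so a gap column is either a loss in the gapped child (the parent
  kept the segment) or a duplication in the other child; a mismatch block is
  a reversal in one child.  The parent is then read off the labeling
  (:func:`infer_parent`) — this is the small-phylogeny initialization step.

* **directed mode** aligns an ancestor ``A`` with a descendant ``X``; every
  operation flows from A to X ([a,-] columns are losses, [-,x] columns are
  duplications with a visible source).  Its cost is the branch cost used by
  the tree driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import cycles as _cycles
from ._dputil import SubstringIndex, has_negative, reversal_extensions
from .median import _materialize, reselect_sources
from .model import (DUP, LOSS, REV, AlignOp, CostScheme, Gene, GeneOrder,
                    History, LabeledAlignment, labeling_cost, replay_history,
                    validate_alignment)

_MATCH, _LOSS_1, _LOSS_2, _DUP_1, _DUP_2, _REV = (
    "match", "loss_first", "loss_second", "dup_first", "dup_second", "rev")

# prefer the loss reading over the duplication on ties: it keeps the parent
# maximal, mirroring the cycle-repair rule that converts duplications into
# losses plus ancestral duplications
_PRIO = {_MATCH: 0, _LOSS_1: 1, _LOSS_2: 1, _REV: 2, _DUP_1: 3, _DUP_2: 3}


@dataclass
class PairAlignmentResult:
    """A feasible two-row labeled alignment plus derived quantities."""

    alignment: LabeledAlignment
    cost: float
    inferred_parent: Optional[GeneOrder]  # sibling mode only
    histories: dict[str, History]


def _pair_dp(U, V, costs: CostScheme, directed: bool):
    """Shared engine.  Rows are (A, X) when directed, else (X, Y)."""
    first_id, second_id = ("A", "X") if directed else ("X", "Y")
    u, v = tuple(U.genes), tuple(V.genes)
    nu, nv = len(u), len(v)
    index = SubstringIndex({first_id: u, second_id: v})
    if directed:
        # only the descendant duplicates; sources visible in A or elsewhere in X
        occ_v = index.max_suffix_occurrence(v, (first_id, second_id),
                                            self_id=second_id)
        occ_u = [0] * (nu + 1)
    else:
        occ_u = index.max_suffix_occurrence(u, (first_id, second_id),
                                            self_id=first_id)
        occ_v = index.max_suffix_occurrence(v, (first_id, second_id),
                                            self_id=second_id)
    signed = has_negative(u, v)

    n_tot = nu + nv
    per = max(costs.cost(kind, ln) for kind in (DUP, LOSS, REV)
              for ln in (1, max(1, n_tot)))
    sentinel = 1.0 + per * (2 * n_tot + 2)

    C = [[sentinel] * (nv + 1) for _ in range(nu + 1)]
    B: list[list] = [[None] * (nv + 1) for _ in range(nu + 1)]
    C[0][0] = 0.0
    for i in range(nu + 1):
        for j in range(nv + 1):
            if i == j == 0:
                continue
            cands: list[tuple[str, int, float]] = []
            if i and j and u[i - 1] == v[j - 1]:
                cands.append((_MATCH, 1, C[i - 1][j - 1]))
            for m in range(1, i + 1):  # [u, -]: loss in the second genome
                cands.append((_LOSS_2, m, C[i - m][j] + costs.loss(m)))
            if not directed:
                for m in range(1, j + 1):  # [-, v]: loss in the first genome
                    cands.append((_LOSS_1, m, C[i][j - m] + costs.loss(m)))
            for m in range(1, occ_u[i] + 1):  # [u, -]: duplication in first
                cands.append((_DUP_1, m, C[i - m][j] + costs.dup(m)))
            for m in range(1, occ_v[j] + 1):  # [-, v]: duplication in second
                cands.append((_DUP_2, m, C[i][j - m] + costs.dup(m)))
            if signed:
                for m in reversal_extensions(u, i, v, j, min(i, j)):
                    cands.append((_REV, m, C[i - m][j - m] + costs.rev(m)))
            best = None
            for case, m, c in cands:
                if c >= sentinel:
                    continue
                key = (c, _PRIO[case], -m)
                if best is None or key < best[0]:
                    best = (key, case, m)
            if best is not None:
                C[i][j] = best[0][0]
                B[i][j] = (best[1], best[2])

    # backtrack
    blocks = []
    i, j = nu, nv
    while (i, j) != (0, 0):
        if B[i][j] is None:
            raise ValueError("no labeled alignment found (unexplainable content)")
        case, m = B[i][j]
        blocks.append((case, m, i, j))
        di, dj = {_MATCH: (1, 1), _REV: (1, 1), _LOSS_2: (1, 0), _DUP_1: (1, 0),
                  _LOSS_1: (0, 1), _DUP_2: (0, 1)}[case]
        i, j = i - di * m, j - dj * m
    blocks.reverse()
    return _pair_blocks_to_alignment(blocks, u, v, first_id, second_id,
                                     directed, index)


def _pair_blocks_to_alignment(blocks, u, v, fid, sid, directed, index):
    row1: list[Optional[Gene]] = []
    row2: list[Optional[Gene]] = []
    ops: list[AlignOp] = []
    pair = frozenset({frozenset((fid, sid))})
    for case, m, i, j in blocks:
        c1 = len(row1)
        cols = (c1, c1 + m)
        useg, vseg = u[i - m:i], v[j - m:j]
        if case in (_MATCH, _REV):
            row1.extend(useg)
            row2.extend(vseg)
        elif case in (_LOSS_2, _DUP_1):
            row1.extend(useg)
            row2.extend([None] * m)
        else:
            row1.extend([None] * m)
            row2.extend(vseg)
        if case == _MATCH:
            continue
        if case == _REV:
            # reversal assigned to the descendant / second branch
            ops.append(AlignOp(REV, cols, sid, pair))
        elif case == _LOSS_2:
            ops.append(AlignOp(LOSS, cols, sid, pair))
        elif case == _LOSS_1:
            ops.append(AlignOp(LOSS, cols, fid, pair))
        elif case == _DUP_1:
            src = _pick(index, useg, prefer=(sid, fid), exclude=(fid, i - m))
            ops.append(AlignOp(DUP, cols, fid, pair, src))
        elif case == _DUP_2:
            src = _pick(index, vseg, prefer=(fid, sid), exclude=(sid, j - m))
            ops.append(AlignOp(DUP, cols, sid, pair, src))
    aln = LabeledAlignment(
        rows={fid: tuple(row1), sid: tuple(row2)},
        row_order=[fid, sid], ops=ops,
        ancestors=frozenset({"A"}) if directed else frozenset())
    reselect_sources(aln, index)
    return aln


def _pick(index: SubstringIndex, seg, prefer, exclude):
    for gid in prefer:
        for g, p in index.occurrences(seg):
            if g == gid and (g, p) != exclude:
                return (g, (p, p + len(seg)))
    raise AssertionError("duplication chosen without a visible source")


def align_siblings(X: GeneOrder, Y: GeneOrder,
                   costs: Optional[CostScheme] = None) -> PairAlignmentResult:
    """Feasible labeled alignment of a cherry, with the parent inferred."""
    costs = costs or CostScheme.unit()
    aln = _pair_dp(X.with_id("X"), Y.with_id("Y"), costs, directed=False)
    aln = _cycles.resolve_cycles(aln)
    issues = validate_alignment(aln)
    if issues:
        raise AssertionError("internal: invalid sibling alignment: "
                             + "; ".join(issues[:5]))
    parent = infer_parent(aln)
    hx = _branch_history(aln, parent, "X")
    hy = _branch_history(aln, parent, "Y")
    if replay_history(parent, hx).genes != tuple(X.genes):
        raise AssertionError("parent history does not replay to X")
    if replay_history(parent, hy).genes != tuple(Y.genes):
        raise AssertionError("parent history does not replay to Y")
    return PairAlignmentResult(alignment=aln, cost=labeling_cost(aln, costs),
                               inferred_parent=parent,
                               histories={"X": hx, "Y": hy})


def align_directed(A: GeneOrder, X: GeneOrder,
                   costs: Optional[CostScheme] = None) -> PairAlignmentResult:
    """Feasible labeled alignment of a branch: every event flows A -> X."""
    costs = costs or CostScheme.unit()
    aln = _pair_dp(A.with_id("A"), X.with_id("X"), costs, directed=True)
    aln = _cycles.resolve_cycles(aln)
    issues = validate_alignment(aln)
    if issues:
        raise AssertionError("internal: invalid directed alignment: "
                             + "; ".join(issues[:5]))
    a_cells = [(c, g) for c, g in enumerate(aln.rows["A"]) if g is not None]
    hist = _materialize(a_cells, [o for o in aln.ops if o.branch == "X"],
                        aln.rows, aln.rows["X"], anc_id="A", desc_id="X")
    if replay_history(A.with_id("A"), hist).genes != tuple(X.genes):
        raise AssertionError("directed history does not replay to X")
    return PairAlignmentResult(alignment=aln, cost=labeling_cost(aln, costs),
                               inferred_parent=None, histories={"X": hist})


def infer_parent(alignment: LabeledAlignment) -> GeneOrder:
    """Parent of a cherry from its feasible labeling.

    Per column: matches are inherited; a loss column keeps the surviving
    child's symbol (the parent had it); a duplication column contributes
    nothing; a reversal column keeps the symbol of the child that did not
    reverse.
    """
    if _cycles.find_cycles(_cycles.build_overlap_graph(alignment)):
        raise ValueError("infeasible (cyclic) alignment")
    rows = alignment.rows
    if set(rows) != {"X", "Y"}:
        raise ValueError("infer_parent expects a sibling alignment")
    by_col: dict[int, AlignOp] = {}
    for op in alignment.ops:
        for c in range(*op.cols):
            by_col[c] = op
    genes = []
    for c in range(alignment.length):
        x, y = rows["X"][c], rows["Y"][c]
        op = by_col.get(c)
        if op is None:
            genes.append(x)  # match
        elif op.kind == LOSS:
            genes.append(x if op.branch == "Y" else y)
        elif op.kind == REV:
            genes.append(y if op.branch == "X" else x)
        # duplication: parent lacks the segment
    return GeneOrder(tuple(genes), "M")


def _branch_history(aln: LabeledAlignment, parent: GeneOrder, branch: str) -> History:
    by_col: dict[int, AlignOp] = {}
    for op in aln.ops:
        for c in range(*op.cols):
            by_col[c] = op
    m_cells = []
    p = 0
    for c in range(aln.length):
        op = by_col.get(c)
        present = (op is None or op.kind == LOSS or op.kind == REV)
        if present:
            m_cells.append((c, parent.genes[p]))
            p += 1
    ops = [o for o in aln.ops if o.branch == branch]
    return _materialize(m_cells, ops, aln.rows, aln.rows[branch],
                        anc_id="M", desc_id=branch)
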