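"""Dynamic-programming heuristic for the 3-star (directed median) problem.

Given a 3-star ``A|XY`` — grandparent assignment ``A`` above a cherry
``X, Y`` — the task is to choose the center genome ``M`` and three branch
histories ``A->M``, ``M->X``, ``M->Y`` of minimum total event cost.  Because
duplications and losses are not symmetric (a duplication read upward is a
loss), the direction of evolution matters and this is not a plain median.

The heuristic reduces the problem to finding a cheap *labeled alignment* of
the three genomes.  A cubic cost table ``C(i, j, k)`` over prefix lengths is
filled by interpreting the last alignment column in all admissible ways
(nine case families: matches, reversals in the center or one child,
duplications shared by the children or private to one, losses in one child,
both, or above the center), backtracking yields a labeled alignment, cycle
resolution repairs it into a feasible one, and the center and its histories
are read off the feasible labeling.  The method is a heuristic: per-column
interpretations are capped at two same-length events and nothing guarantees
global optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import cycles as _cycles
from ._dputil import (SubstringIndex, has_negative, lcs_suffix_table,
                      reversal_extensions)
from .model import (DUP, LOSS, REV, AlignOp, CostScheme, Gene, GeneOrder,
                    History, LabeledAlignment, Operation, Segment,
                    StarInstance, labeling_cost, reverse_of, validate_alignment)

# Case identifiers.  Comments give the column shape; symmetric variants are
# distinct cases so that backtracking is unambiguous.
MATCH = "match"            # [a,a,a]
REV_M = "rev_M"            # [a,x,x]  reversal above the center
REV_X = "rev_X"            # [a,x,a]  reversal on the X branch
REV_Y = "rev_Y"            # [a,a,y]
DUP_M = "dup_M"            # [-,x,x]  duplication above the center
REVM_LOSS_Y = "revM_loss_Y"  # [a,x,-]  reversal above center + loss in Y
REVM_LOSS_X = "revM_loss_X"  # [a,-,y]
DUPM_REV_Y = "dupM_rev_Y"  # [-,x,y]  duplication above center + reversal in Y
DUPM_REV_X = "dupM_rev_X"  # [-,x,y]  (center matches Y)
LOSS_X = "loss_X"          # [a,-,a]  loss on the X branch
LOSS_Y = "loss_Y"          # [a,a,-]
LOSS_A = "loss_A"          # [a,-,-]  loss above the center
DUP_X = "dup_X"            # [-,x,-]  duplication on the X branch
DUP_Y = "dup_Y"            # [-,-,y]

# Deterministic tie-break: prefer interpretations keeping the center close
# to A — matches, then losses, then the shared duplication, then reversals,
# then solo duplications, then the compound cases.
CASE_PRIORITY = {
    MATCH: 0,
    LOSS_X: 1, LOSS_Y: 1, LOSS_A: 1,
    DUP_M: 2,
    REV_M: 3, REV_X: 3, REV_Y: 3,
    DUP_X: 4, DUP_Y: 4,
    REVM_LOSS_Y: 5, REVM_LOSS_X: 5, DUPM_REV_Y: 5, DUPM_REV_X: 5,
}

# prefix characters consumed from (A, X, Y) per unit of extension length
_CONSUME = {
    MATCH: (1, 1, 1), REV_M: (1, 1, 1), REV_X: (1, 1, 1), REV_Y: (1, 1, 1),
    DUP_M: (0, 1, 1), REVM_LOSS_Y: (1, 1, 0), REVM_LOSS_X: (1, 0, 1),
    DUPM_REV_Y: (0, 1, 1), DUPM_REV_X: (0, 1, 1),
    LOSS_X: (1, 0, 1), LOSS_Y: (1, 1, 0), LOSS_A: (1, 0, 0),
    DUP_X: (0, 1, 0), DUP_Y: (0, 0, 1),
}


@dataclass
class DPTable:
    """Cost table ``C`` over prefix lengths plus one backpointer per cell."""

    cost: list  # (|A|+1) x (|X|+1) x (|Y|+1) nested lists
    back: list  # same shape; entries (case, m) or None
    instance: StarInstance
    sentinel: float
    context: "_StarContext"

    def final_cost(self) -> float:
        return self.cost[len(self.instance.A)][len(self.instance.X)][len(self.instance.Y)]


@dataclass
class StarSolution:
    """Center genome plus the three branch histories and their total cost."""

    center: GeneOrder
    histories: dict[str, History]  # "M": A->M, "X": M->X, "Y": M->Y
    cost: float
    alignment: LabeledAlignment


class _StarContext:
    """Per-instance precomputed tables shared by all case evaluations."""

    def __init__(self, inst: StarInstance):
        A, X, Y = inst.A.genes, inst.X.genes, inst.Y.genes
        self.A, self.X, self.Y = A, X, Y
        self.costs = inst.costs
        self.lcs_ax = lcs_suffix_table(A, X)
        self.lcs_ay = lcs_suffix_table(A, Y)
        self.lcs_xy = lcs_suffix_table(X, Y)
        self.index = SubstringIndex({"A": A, "X": X, "Y": Y})
        # longest suffix of X[:j] occurring in A (for the shared duplication)
        self.occA_x = self.index.max_suffix_occurrence(X, ("A",))
        self.occA_y = self.index.max_suffix_occurrence(Y, ("A",))
        # longest suffix of X[:j] occurring anywhere visible (solo duplication);
        # an occurrence of the segment at its own position does not count
        self.occAXY_x = self.index.max_suffix_occurrence(X, ("A", "X", "Y"),
                                                         self_id="X")
        self.occAXY_y = self.index.max_suffix_occurrence(Y, ("A", "X", "Y"),
                                                         self_id="Y")
        self.signed = has_negative(A, X, Y)


def evaluate_cases(i: int, j: int, k: int, table: DPTable) -> list[tuple[str, int, float]]:
    """Candidate interpretations of the last column block at cell (i, j, k).

    Returns ``(case, extension length m, total cost C[predecessor] + event
    cost)`` for every applicable case and admissible extension; inapplicable
    cases simply yield nothing (their cost would be the sentinel).
    """
    ctx = table.context
    C = table.cost
    costs = ctx.costs
    A, X, Y = ctx.A, ctx.X, ctx.Y
    out: list[tuple[str, int, float]] = []

    if i and j and k and A[i - 1] == X[j - 1] == Y[k - 1]:
        out.append((MATCH, 1, C[i - 1][j - 1][k - 1]))

    # losses on one child branch: the lost segment must be a common suffix of
    # the grandparent prefix and the surviving child's prefix
    if i and k and A[i - 1] == Y[k - 1]:
        lmax = min(ctx.lcs_ay[i][k], i, k)
        for m in range(1, lmax + 1):
            out.append((LOSS_X, m, C[i - m][j][k - m] + costs.loss(m)))
    if i and j and A[i - 1] == X[j - 1]:
        lmax = min(ctx.lcs_ax[i][j], i, j)
        for m in range(1, lmax + 1):
            out.append((LOSS_Y, m, C[i - m][j - m][k] + costs.loss(m)))
    # loss above the center: any suffix of A[:i]
    for m in range(1, i + 1):
        out.append((LOSS_A, m, C[i - m][j][k] + costs.loss(m)))

    # shared duplication: identical child suffixes with a source in A
    if j and k and X[j - 1] == Y[k - 1]:
        lmax = min(ctx.lcs_xy[j][k], ctx.occA_x[j])
        for m in range(1, lmax + 1):
            out.append((DUP_M, m, C[i][j - m][k - m] + costs.dup(m)))

    # solo duplications: suffix with a visible occurrence elsewhere
    for m in range(1, ctx.occAXY_x[j] + 1):
        out.append((DUP_X, m, C[i][j - m][k] + costs.dup(m)))
    for m in range(1, ctx.occAXY_y[k] + 1):
        out.append((DUP_Y, m, C[i][j][k - m] + costs.dup(m)))

    if ctx.signed:
        out.extend(_reversal_cases(i, j, k, table))
    return out


def _reversal_cases(i, j, k, table: DPTable) -> list[tuple[str, int, float]]:
    ctx = table.context
    C = table.cost
    costs = ctx.costs
    A, X, Y = ctx.A, ctx.X, ctx.Y
    out = []
    # reversal above the center: identical child suffixes, reverse of A's
    for m in reversal_extensions(A, i, X, j, min(i, j, k)):
        if ctx.lcs_xy[j][k] >= m:
            out.append((REV_M, m, C[i - m][j - m][k - m] + costs.rev(m)))
    # reversal on one child branch
    for m in reversal_extensions(A, i, X, j, min(i, j, k)):
        if ctx.lcs_ay[i][k] >= m:
            out.append((REV_X, m, C[i - m][j - m][k - m] + costs.rev(m)))
    for m in reversal_extensions(A, i, Y, k, min(i, j, k)):
        if ctx.lcs_ax[i][j] >= m:
            out.append((REV_Y, m, C[i - m][j - m][k - m] + costs.rev(m)))
    # reversal above the center combined with a loss on one child branch
    for m in reversal_extensions(A, i, X, j, min(i, j)):
        out.append((REVM_LOSS_Y, m,
                    C[i - m][j - m][k] + costs.rev(m) + costs.loss(m)))
    for m in reversal_extensions(A, i, Y, k, min(i, k)):
        out.append((REVM_LOSS_X, m,
                    C[i - m][j][k - m] + costs.rev(m) + costs.loss(m)))
    # duplication above the center combined with a reversal on one branch
    for m in reversal_extensions(X, j, Y, k, min(j, k)):
        if ctx.occA_x[j] >= m:
            out.append((DUPM_REV_Y, m,
                        C[i][j - m][k - m] + costs.dup(m) + costs.rev(m)))
        if ctx.occA_y[k] >= m:
            out.append((DUPM_REV_X, m,
                        C[i][j - m][k - m] + costs.dup(m) + costs.rev(m)))
    return out


def compute_dp(instance: StarInstance) -> DPTable:
    """Fill the cubic cost table in lexicographic order of prefix lengths.

    Cells minimize cost first; among equal-cost interpretations the table
    carries a secondary count of privately duplicated genes (cases with a
    target in one child only), so backtracking prefers labelings with fewer
    leaf-internal duplications — the only operations that can form cycles.
    """
    ctx = _StarContext(instance)
    na, nx, ny = len(ctx.A), len(ctx.X), len(ctx.Y)
    sentinel = instance.unreachable_cost()
    cost = [[[sentinel] * (ny + 1) for _ in range(nx + 1)] for _ in range(na + 1)]
    pen = [[[0] * (ny + 1) for _ in range(nx + 1)] for _ in range(na + 1)]
    back = [[[None] * (ny + 1) for _ in range(nx + 1)] for _ in range(na + 1)]
    cost[0][0][0] = 0.0
    table = DPTable(cost, back, instance, sentinel, ctx)
    for i in range(na + 1):
        for j in range(nx + 1):
            for k in range(ny + 1):
                if i == j == k == 0:
                    continue
                best = None
                for case, m, c in evaluate_cases(i, j, k, table):
                    if c >= sentinel:
                        continue
                    da, dx, dy = _CONSUME[case]
                    p = pen[i - da * m][j - dx * m][k - dy * m]
                    if case in (DUP_X, DUP_Y):
                        p += m
                    key = (c, p, CASE_PRIORITY[case], -m)
                    if best is None or key < best[0]:
                        best = (key, case, m)
                if best is not None:
                    cost[i][j][k] = best[0][0]
                    pen[i][j][k] = best[0][1]
                    back[i][j][k] = (best[1], best[2])
    return table


@dataclass
class _Block:
    case: str
    m: int
    i: int  # cell the block was chosen at (prefix lengths *after* the block)
    j: int
    k: int


def backtrack(table: DPTable, instance: StarInstance) -> LabeledAlignment:
    """Reconstruct the labeled three-row alignment chosen by the table."""
    na, nx, ny = len(instance.A), len(instance.X), len(instance.Y)
    if table.cost[na][nx][ny] >= table.sentinel:
        raise ValueError("no labeled alignment found (unexplainable content)")
    blocks: list[_Block] = []
    i, j, k = na, nx, ny
    while (i, j, k) != (0, 0, 0):
        bp = table.back[i][j][k]
        if bp is None:
            raise ValueError(f"corrupted backpointer chain at {(i, j, k)}")
        case, m = bp
        blocks.append(_Block(case, m, i, j, k))
        da, dx, dy = _CONSUME[case]
        i, j, k = i - da * m, j - dx * m, k - dy * m
    blocks.reverse()
    return _blocks_to_alignment(blocks, table.context)


def _blocks_to_alignment(blocks: list[_Block], ctx: _StarContext) -> LabeledAlignment:
    A, X, Y = ctx.A, ctx.X, ctx.Y
    rowA: list[Optional[Gene]] = []
    rowX: list[Optional[Gene]] = []
    rowY: list[Optional[Gene]] = []
    ops: list[AlignOp] = []
    pk = lambda a, b: frozenset((a, b))

    for b in blocks:
        c1 = len(rowA)
        m = b.m
        asg = A[b.i - m:b.i] if _CONSUME[b.case][0] else ()
        xsg = X[b.j - m:b.j] if _CONSUME[b.case][1] else ()
        ysg = Y[b.k - m:b.k] if _CONSUME[b.case][2] else ()
        rowA.extend(asg if asg else [None] * m)
        rowX.extend(xsg if xsg else [None] * m)
        rowY.extend(ysg if ysg else [None] * m)
        cols = (c1, c1 + m)
        cs = b.case
        if cs == MATCH:
            continue
        if cs == REV_M:
            ops.append(AlignOp(REV, cols, "M",
                               frozenset({pk("A", "X"), pk("A", "Y")})))
        elif cs == REV_X:
            ops.append(AlignOp(REV, cols, "X",
                               frozenset({pk("A", "X"), pk("X", "Y")})))
        elif cs == REV_Y:
            ops.append(AlignOp(REV, cols, "Y",
                               frozenset({pk("A", "Y"), pk("X", "Y")})))
        elif cs == DUP_M:
            src = _pick_source(ctx, xsg, prefer=("A",))
            ops.append(AlignOp(DUP, cols, "M",
                               frozenset({pk("A", "X"), pk("A", "Y")}), src))
        elif cs == REVM_LOSS_Y:
            ops.append(AlignOp(REV, cols, "M", frozenset({pk("A", "X")})))
            ops.append(AlignOp(LOSS, cols, "Y",
                               frozenset({pk("A", "Y"), pk("X", "Y")})))
        elif cs == REVM_LOSS_X:
            ops.append(AlignOp(REV, cols, "M", frozenset({pk("A", "Y")})))
            ops.append(AlignOp(LOSS, cols, "X",
                               frozenset({pk("A", "X"), pk("X", "Y")})))
        elif cs == DUPM_REV_Y:
            src = _pick_source(ctx, xsg, prefer=("A",))
            ops.append(AlignOp(DUP, cols, "M", frozenset({pk("A", "X")}), src))
            ops.append(AlignOp(REV, cols, "Y",
                               frozenset({pk("A", "Y"), pk("X", "Y")})))
        elif cs == DUPM_REV_X:
            src = _pick_source(ctx, ysg, prefer=("A",))
            ops.append(AlignOp(DUP, cols, "M", frozenset({pk("A", "Y")}), src))
            ops.append(AlignOp(REV, cols, "X",
                               frozenset({pk("A", "X"), pk("X", "Y")})))
        elif cs == LOSS_X:
            ops.append(AlignOp(LOSS, cols, "X",
                               frozenset({pk("A", "X"), pk("X", "Y")})))
        elif cs == LOSS_Y:
            ops.append(AlignOp(LOSS, cols, "Y",
                               frozenset({pk("A", "Y"), pk("X", "Y")})))
        elif cs == LOSS_A:
            ops.append(AlignOp(LOSS, cols, "M",
                               frozenset({pk("A", "X"), pk("A", "Y")})))
        elif cs == DUP_X:
            src = _pick_source(ctx, xsg, prefer=("A", "Y", "X"),
                               exclude=("X", b.j - m))
            ops.append(AlignOp(DUP, cols, "X",
                               frozenset({pk("A", "X"), pk("X", "Y")}), src))
        elif cs == DUP_Y:
            src = _pick_source(ctx, ysg, prefer=("A", "X", "Y"),
                               exclude=("Y", b.k - m))
            ops.append(AlignOp(DUP, cols, "Y",
                               frozenset({pk("A", "Y"), pk("X", "Y")}), src))
        else:  # pragma: no cover
            raise AssertionError(f"unknown case {cs}")

    aln = LabeledAlignment(
        rows={"A": tuple(rowA), "X": tuple(rowX), "Y": tuple(rowY)},
        row_order=["A", "X", "Y"],
        ops=ops,
        ancestors=frozenset({"A"}),
    )
    reselect_sources(aln, ctx.index)
    return aln


def reselect_sources(aln: LabeledAlignment, index) -> None:
    """Re-point leaf-sourced duplications at cycle-safe occurrences.

    The recurrences only require *some* visible occurrence of a duplicated
    segment; which occurrence serves as the source is free.  Preferring an
    occurrence in the ancestor, then one disjoint from every duplication
    target, removes most overlap cycles before the repair step has to pay
    for them.
    """
    leaf_rows = set(aln.rows) - set(aln.ancestors)
    c2p = {rid: aln.col_to_pos(rid) for rid in aln.rows}
    targets: dict[str, list[tuple[int, int]]] = {r: [] for r in aln.rows}
    for op in aln.ops:
        if op.kind == DUP and op.branch in leaf_rows:
            pos = [c2p[op.branch][c] for c in range(*op.cols)
                   if c in c2p[op.branch]]
            targets[op.branch].append((pos[0], pos[-1] + 1))
    for idx, op in enumerate(aln.ops):
        if op.kind != DUP or op.source is None:
            continue
        if op.source[0] not in leaf_rows:
            continue
        seg = _op_content(aln, op)
        best = None
        for gid, p in index.occurrences(seg):
            iv = (p, p + len(seg))
            own = (op.branch == gid and
                   any(max(iv[0], a) < min(iv[1], b)
                       for a, b in _own_target(aln, op, c2p)))
            if own:
                continue
            if gid not in leaf_rows:
                best = (0, gid, iv)
                break
            clear = all(not (max(iv[0], a) < min(iv[1], b))
                        for a, b in targets.get(gid, []))
            rank = 1 if clear else 2
            if best is None or rank < best[0]:
                best = (rank, gid, iv)
        if best is not None and best[0] < 2:
            aln.ops[idx] = AlignOp(op.kind, op.cols, op.branch, op.covers,
                                   (best[1], best[2]))


def _own_target(aln, op, c2p) -> list[tuple[int, int]]:
    pos = [c2p[op.branch][c] for c in range(*op.cols) if c in c2p[op.branch]]
    return [(pos[0], pos[-1] + 1)] if pos else []


def _op_content(aln: LabeledAlignment, op: AlignOp) -> Segment:
    row = op.branch if op.branch in aln.rows else None
    if row is None:  # duplication above the center: use a visible image
        for pair in op.covers:
            for rid in pair:
                if rid in aln.rows and rid not in aln.ancestors:
                    cells = [aln.rows[rid][c] for c in range(*op.cols)]
                    genes = tuple(g for g in cells if g is not None)
                    if len(genes) == op.length:
                        return genes
        raise AssertionError("no visible image for center duplication")
    cells = [aln.rows[row][c] for c in range(*op.cols)]
    return tuple(g for g in cells if g is not None)


def _pick_source(ctx: _StarContext, seg: Segment, prefer: tuple[str, ...],
                 exclude: Optional[tuple[str, int]] = None) -> tuple[str, tuple[int, int]]:
    occ = ctx.index.occurrences(seg)
    for gid in prefer:
        for g, p in occ:
            if g == gid and (g, p) != exclude:
                return (g, (p, p + len(seg)))
    raise AssertionError("duplication chosen without a visible source")


# ---------------------------------------------------------------------------
# center extraction

def extract_center(alignment: LabeledAlignment, instance: StarInstance) -> StarSolution:
    """Read the center genome and the three branch histories off a feasible
    labeled alignment.

    Per column the center is: the shared symbol on matches; the surviving
    child's symbol under a branch loss or branch reversal; the duplicated
    content under a duplication above the center; absent under a loss above
    the center or a duplication private to one child.  Histories are then
    materialized branch by branch and checked by replay.
    """
    if _cycles.find_cycles(_cycles.build_overlap_graph(alignment)):
        raise ValueError("alignment is infeasible (contains cycles); "
                         "run resolve_cycles first")
    lam = alignment.length
    rows = alignment.rows
    by_col: dict[int, list[AlignOp]] = {c: [] for c in range(lam)}
    for op in alignment.ops:
        for c in range(*op.cols):
            by_col[c].append(op)

    rowM: list[Optional[Gene]] = []
    for c in range(lam):
        a, x, y = rows["A"][c], rows["X"][c], rows["Y"][c]
        here = by_col[c]
        center_ops = [o for o in here if o.branch == "M"]
        if center_ops:
            kinds = {o.kind for o in center_ops}
            if LOSS in kinds:
                rowM.append(None)
            else:
                # duplication or reversal above the center: the center agrees
                # with the child named in the op's covered pairs
                cov = center_ops[0].covers
                if frozenset({"A", "X"}) in cov and x is not None:
                    rowM.append(x)
                else:
                    rowM.append(y if y is not None else x)
        elif not here:
            rowM.append(x if x is not None else (y if y is not None else a))
        else:
            op = here[0]
            if op.kind == DUP:  # private child duplication
                rowM.append(None)
            elif op.branch == "X":  # loss/reversal on X branch: center follows A/Y
                rowM.append(a if a is not None else y)
            else:
                rowM.append(a if a is not None else x)

    center = GeneOrder(tuple(g for g in rowM if g is not None), "M")

    a_cells = [(c, g) for c, g in enumerate(rows["A"]) if g is not None]
    m_cells = [(c, g) for c, g in enumerate(rowM) if g is not None]
    x_cells = [(c, g) for c, g in enumerate(rows["X"]) if g is not None]
    y_cells = [(c, g) for c, g in enumerate(rows["Y"]) if g is not None]

    hist_M = _materialize(a_cells, [o for o in alignment.ops if o.branch == "M"],
                          rows, rowM, anc_id="A", desc_id="M")
    hist_X = _materialize(m_cells, [o for o in alignment.ops if o.branch == "X"],
                          rows, rows["X"], anc_id="M", desc_id="X")
    hist_Y = _materialize(m_cells, [o for o in alignment.ops if o.branch == "Y"],
                          rows, rows["Y"], anc_id="M", desc_id="Y")

    from .model import replay_history
    got_m = replay_history(instance.A, hist_M)
    if got_m.genes != center.genes:
        raise AssertionError("A->M history does not replay to the center")
    if replay_history(center, hist_X).genes != instance.X.genes:
        raise AssertionError("M->X history does not replay to X")
    if replay_history(center, hist_Y).genes != instance.Y.genes:
        raise AssertionError("M->Y history does not replay to Y")

    cost = labeling_cost(alignment, instance.costs)
    return StarSolution(center=center,
                        histories={"M": hist_M, "X": hist_X, "Y": hist_Y},
                        cost=cost, alignment=alignment)


def _materialize(anc_cells: list[tuple[int, Optional[Gene]]], ops: list[AlignOp],
                 rows: dict, desc_row, anc_id: str, desc_id: str) -> History:
    """Turn branch alignment-ops into a replayable genome-coordinate history.

    Events are emitted right-to-left over alignment columns so that the
    coordinates recorded for each event are valid in the intermediate genome
    at its application time.
    """
    current = list(anc_cells)  # (column, gene), sorted by column
    history: History = []
    for op in sorted(ops, key=lambda o: -o.cols[0]):
        c1, c2 = op.cols
        lo = _bisect_col(current, c1)
        hi = _bisect_col(current, c2)
        if op.kind == LOSS:
            if hi - lo != op.length:
                raise AssertionError("loss does not cover a contiguous "
                                     "ancestor segment")
            history.append(Operation(LOSS, op.length,
                                     source=(anc_id, (lo, hi))))
            del current[lo:hi]
        elif op.kind == REV:
            if hi - lo != op.length:
                raise AssertionError("reversal does not cover a contiguous "
                                     "ancestor segment")
            seg = [g for _, g in current[lo:hi]]
            flipped = reverse_of(seg)
            for t in range(hi - lo):
                current[lo + t] = (current[lo + t][0], flipped[t])
            history.append(Operation(REV, op.length,
                                     source=(anc_id, (lo, hi)),
                                     target=(anc_id, (lo, hi))))
        else:  # duplication: descendant gains content at these columns
            content = tuple(desc_row[c] for c in range(c1, c2)
                            if desc_row[c] is not None)
            if len(content) != op.length:
                raise AssertionError("duplication target is not contiguous "
                                     "in the descendant")
            src = op.source if op.source is not None else (anc_id, (0, op.length))
            history.append(Operation(DUP, op.length, source=src,
                                     target=(desc_id, (lo, lo + op.length)),
                                     content=content))
            current[lo:lo] = [(c1 + t, content[t]) for t in range(op.length)]
    return history


def _bisect_col(cells: list[tuple[int, Gene]], col: int) -> int:
    import bisect
    return bisect.bisect_left(cells, col, key=lambda e: e[0])


def solve_star(instance: StarInstance) -> StarSolution:
    """Full 3-star pipeline: DP, backtracking, cycle repair, extraction.

    The returned cost is the sum of the three branch costs around the
    extracted center.  After extraction each branch is re-aligned with the
    directed pairwise aligner; when that decomposition is cheaper than the
    three-row labeling (the pairwise view can merge events that the
    column-block recurrences had to split), its histories and cost are kept.
    """
    table = compute_dp(instance)
    aln = backtrack(table, instance)
    aln = _cycles.resolve_cycles(aln, instance)
    issues = validate_alignment(aln)
    if issues:
        raise AssertionError("internal: resolved alignment invalid: "
                             + "; ".join(issues[:5]))
    sol = extract_center(aln, instance)

    from .pairwise import align_directed  # local import: pairwise uses median
    bm = align_directed(instance.A, sol.center, instance.costs)
    bx = align_directed(sol.center, instance.X, instance.costs)
    by = align_directed(sol.center, instance.Y, instance.costs)
    alt = bm.cost + bx.cost + by.cost
    if alt < sol.cost - 1e-9:
        return StarSolution(center=sol.center,
                            histories={"M": bm.histories["X"],
                                       "X": bx.histories["X"],
                                       "Y": by.histories["X"]},
                            cost=alt, alignment=sol.alignment)
    return sol
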