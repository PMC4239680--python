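"""Cycle detection and repair for labeled alignments.

A labeled alignment corresponds to a realizable (visible) history only when
its operations are free of *cycles*: circular chains of operations in which
each operation's target overlaps the next operation's source.  Only
duplications whose source and target both lie in observed (non-ancestral)
genomes can take part in a cycle — a loss has an empty target and a reversal
in a cycle would force a doubly-covered column.

Repair follows the minimum-decomposition rule: pick the cycle member whose
target string splits into the fewest substrings that each occur in the
grandparent A, relabel that target as a loss in the sibling genome plus one
duplication from A per part.  This removes a leaf-sourced duplication from
the overlap graph at each step, so the repair terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .model import (DUP, LOSS, AlignOp, Gene, GeneOrder, LabeledAlignment,
                    Segment, StarInstance)


class UndecomposableError(ValueError):
    """A target string contains a gene with no visible source occurrence."""


@dataclass
class OverlapGraph:
    """Directed overlap graph over leaf-internal duplications.

    Nodes are the alignment's duplication operations whose target row and
    source genome are both non-ancestral; there is an edge ``p -> q`` when
    ``p``'s target interval overlaps ``q``'s source interval in the same
    genome.  Interval intersection is used as the overlap test: any overlap
    means ``q`` copied genes that exist only once ``p`` has happened.
    """

    nx_graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def operations(self) -> list[AlignOp]:
        return list(self.nx_graph.nodes)


def _target_interval(alignment: LabeledAlignment, op: AlignOp) -> tuple[str, tuple[int, int]]:
    """Genome-coordinate interval of the columns an op writes in its row."""
    row = op.branch
    c2p = alignment.col_to_pos(row)
    pos = [c2p[c] for c in range(*op.cols) if c in c2p]
    return row, (pos[0], pos[-1] + 1)


def build_overlap_graph(alignment: LabeledAlignment) -> OverlapGraph:
    leaf_rows = set(alignment.rows) - set(alignment.ancestors)
    nodes = []
    for op in alignment.ops:
        if op.kind != DUP or op.branch not in leaf_rows:
            continue
        if op.source is None or op.source[0] not in leaf_rows:
            continue
        nodes.append(op)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    targets = {op: _target_interval(alignment, op) for op in nodes}
    for p in nodes:
        tg, (t1, t2) = targets[p]
        for q in nodes:
            sg, (s1, s2) = q.source
            if tg == sg and max(t1, s1) < min(t2, s2):
                g.add_edge(p, q)
    return OverlapGraph(g)


def find_cycles(graph: OverlapGraph) -> list[list[AlignOp]]:
    """One elementary cycle per non-trivial strongly connected component."""
    out: list[list[AlignOp]] = []
    g = graph.nx_graph
    for comp in nx.strongly_connected_components(g):
        comp = list(comp)
        if len(comp) == 1 and not g.has_edge(comp[0], comp[0]):
            continue
        edges = nx.find_cycle(g.subgraph(comp))
        cycle = [e[0] for e in edges]
        for op in cycle:  # every cycle member must be a duplication
            assert op.kind == DUP, "non-duplication operation in a cycle"
        out.append(cycle)
    return out


def min_decomposition(Z: Sequence[Gene], A: GeneOrder | Sequence[Gene]) -> list[Segment]:
    """Split Z into the fewest parts that each occur as a substring of A.

    Computed as a shortest path over cut positions of Z (an edge spans a
    substring occurring in A); reconstruction prefers leftmost-longest parts
    for determinism.  Raises :class:`UndecomposableError` when some gene of
    Z never occurs in A.
    """
    z = tuple(Z)
    if not z:
        raise ValueError("empty target string")
    a = tuple(A.genes if isinstance(A, GeneOrder) else A)
    subs = set()
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            subs.add(a[i:j])
    L = len(z)
    INF = L + 1
    dist = [INF] * (L + 1)
    dist[L] = 0
    for u in range(L - 1, -1, -1):
        for v in range(u + 1, L + 1):
            if z[u:v] in subs and 1 + dist[v] < dist[u]:
                dist[u] = 1 + dist[v]
    if dist[0] >= INF:
        missing = [g.token() for g in z if (g,) not in subs]
        raise UndecomposableError(
            f"no decomposition: gene(s) {missing} never occur in the source")
    parts = []
    u = 0
    while u < L:
        v = max(w for w in range(u + 1, L + 1)
                if z[u:w] in subs and dist[w] == dist[u] - 1)
        parts.append(z[u:v])
        u = v
    return parts


def resolve_cycles(alignment: LabeledAlignment,
                   instance: Optional[StarInstance] = None) -> LabeledAlignment:
    """Repair a labeled alignment until its overlap graph is cycle-free.

    Idempotent on feasible input.  Three repair modes, chosen from the rows
    present:

    * three rows A, X, Y (the 3-star): the chosen target is promoted into
      the center — one loss in the sibling plus per-part duplications from A;
    * sibling pair X, Y: the target is relabeled as a loss in the sibling
      (the free parent absorbs the segment);
    * directed pair A, X: the duplication is re-sourced from A, split into
      the minimum number of A-substrings.
    """
    aln = alignment
    guard = 0
    while True:
        cyc = find_cycles(build_overlap_graph(aln))
        if not cyc:
            return aln
        guard += 1
        if guard > len(aln.ops) + len(alignment.ops) + 1:  # pragma: no cover
            raise RuntimeError("cycle resolution failed to terminate")
        cyc.sort(key=lambda ops: sum(o.length for o in ops))
        aln = _repair_one(aln, cyc[0])


def _repair_one(aln: LabeledAlignment, cycle: list[AlignOp]) -> LabeledAlignment:
    star = "A" in aln.rows and len(aln.rows) == 3
    directed = "A" in aln.rows and len(aln.rows) == 2
    anc = aln.ungapped("A") if "A" in aln.rows else None

    if star or directed:
        # choose the member with the cheapest decomposition over A
        best = None
        for op in cycle:
            z = _target_string(aln, op)
            try:
                parts = min_decomposition(z, anc)
            except UndecomposableError:
                continue
            sources = _anchored_sources(parts, anc)
            key = (len(parts), 0 if op.branch == "X" else 1, op.cols[0])
            if best is None or key < best[0]:
                best = (key, op, parts, sources)
        if best is None:
            # fallback: per-gene duplications sourced wherever each gene
            # occurs — A preferred, then the other leaf, then elsewhere in
            # the same leaf
            op = min(cycle, key=lambda o: (0 if o.branch == "X" else 1,
                                           o.cols[0]))
            parts = [(g,) for g in _target_string(aln, op)]
            sources = _fallback_sources(aln, op, parts, anc)
        else:
            _, op, parts, sources = best
    else:
        op = min(cycle, key=lambda o: (o.branch, o.cols[0]))
        parts, sources = [], []

    ops = [o for o in aln.ops if o is not op]
    other = ({"X", "Y"} - {op.branch}).pop() if op.branch in ("X", "Y") else None
    pk = lambda a, b: frozenset((a, b))

    if star:
        c = op.cols[0]
        for part, src in zip(parts, sources):
            ops.append(AlignOp(DUP, (c, c + len(part)), "M",
                               frozenset({pk("A", op.branch)}), src))
            c += len(part)
        ops.append(AlignOp(LOSS, op.cols, other,
                           frozenset({pk(op.branch, other)})))
    elif directed:
        c = op.cols[0]
        for part, src in zip(parts, sources):
            ops.append(AlignOp(DUP, (c, c + len(part)), "X",
                               frozenset({pk("A", "X")}), src))
            c += len(part)
    else:  # sibling pair: the free parent absorbs the segment
        ops.append(AlignOp(LOSS, op.cols, other,
                           frozenset({pk(op.branch, other)})))

    return LabeledAlignment(rows=dict(aln.rows), row_order=list(aln.row_order),
                            ops=ops, ancestors=aln.ancestors)


def _anchored_sources(parts: list[Segment], anc: GeneOrder) -> list[tuple[str, tuple[int, int]]]:
    out = []
    for part in parts:
        p = _find_in(anc, part)
        out.append(("A", (p, p + len(part))))
    return out


def _fallback_sources(aln: LabeledAlignment, op: AlignOp,
                      parts: list[Segment], anc: GeneOrder):
    """Per-gene sources: A first, then leaf occurrences outside duplication
    targets, then any occurrence other than the gene's own position."""
    leaf_rows = [r for r in aln.row_order if r not in aln.ancestors]
    dup_regions: dict[str, list[tuple[int, int]]] = {r: [] for r in leaf_rows}
    for o in aln.ops:
        if o.kind == DUP and o.branch in leaf_rows:
            row, iv = _op_target_interval(aln, o)
            dup_regions[row].append(iv)
    own_row, own_iv = _op_target_interval(aln, op)
    ungapped = {r: aln.ungapped(r).genes for r in leaf_rows}
    other = [r for r in leaf_rows if r != op.branch]

    sources = []
    for offset, part in enumerate(parts):
        gene = part[0]
        src = None
        if anc is not None:
            p = _find_in(anc, part, missing_ok=True)
            if p is not None:
                src = ("A", (p, p + 1))
        if src is None:
            rows_pref = other + [op.branch]
            candidates = []
            for r in rows_pref:
                for p, g in enumerate(ungapped[r]):
                    if g != gene:
                        continue
                    if r == own_row and own_iv[0] <= p < own_iv[1]:
                        continue  # the gene's own position
                    outside = all(not (a <= p < b) for a, b in dup_regions[r])
                    candidates.append((0 if outside else 1,
                                       rows_pref.index(r), p, r))
            if candidates:
                _, _, p, r = min(candidates)
                src = (r, (p, p + 1))
        if src is None:
            raise UndecomposableError(
                f"cycle cannot be repaired: gene {gene.token()} has no "
                "source occurrence")
        sources.append(src)
    return sources


def _op_target_interval(aln: LabeledAlignment, op: AlignOp) -> tuple[str, tuple[int, int]]:
    c2p = aln.col_to_pos(op.branch)
    pos = [c2p[c] for c in range(*op.cols) if c in c2p]
    return op.branch, (pos[0], pos[-1] + 1)


def _target_string(aln: LabeledAlignment, op: AlignOp) -> Segment:
    return tuple(g for c in range(*op.cols)
                 for g in [aln.rows[op.branch][c]] if g is not None)


def _find_in(anc: GeneOrder, part: Segment, missing_ok: bool = False) -> Optional[int]:
    a = anc.genes
    m = len(part)
    for p in range(len(a) - m + 1):
        if a[p:p + m] == tuple(part):
            return p
    if missing_ok:
        return None
    raise UndecomposableError("part has no occurrence in A")
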