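"""Exhaustive exact solvers for tiny pairwise and 3-star instances.

The enumerator searches over *visible histories* directly, via their
one-to-one correspondence with feasible labeled alignments: columns are
generated left to right, open events (loss runs, duplication targets) are
carried as search state, and iterative deepening on the total cost returns
the optimum together with a witness alignment.  Candidate labelings whose
duplication sources cannot be arranged acyclically are rejected and the
search continues, so the result is feasible by construction.

Scope and guarantees:

* the 3-star solver covers the duplication + loss model on unsigned
  genomes (signed input is rejected); the pair solver additionally handles
  reversal blocks;
* duplication costs must be length-independent and loss costs
  non-decreasing and subadditive (both default schemes qualify);
* loss and duplication events are grouped across alignment columns by
  contiguity in the genome they act on (a single event may span columns
  interleaved with other rows' insertions), so event counting follows the
  model, not the column layout;
* the returned witness splits events at alignment-column gaps for
  representability, so it certifies feasibility; its labeling cost can be
  higher than the reported (exact) cost exactly when events were split.

The solver refuses instances exceeding its :class:`OracleBudget` rather
than silently degrading; it exists for validation, not for production runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

from ._dputil import SubstringIndex, has_negative, reverse_of
from .model import (DUP, LOSS, REV, AlignOp, CostScheme, Gene, GeneOrder,
                    LabeledAlignment, Segment)


class OracleBudgetError(RuntimeError):
    """The instance exceeds the oracle's enumeration budget."""


class OracleInfeasibleError(ValueError):
    """No visible history exists (e.g. a gene family with no source)."""


@dataclass(frozen=True)
class OracleBudget:
    max_genome_len: int = 40
    max_total_len: int = 110
    max_cost: int = 16          # iterative-deepening ceiling
    max_nodes: int = 6_000_000  # search-tree node ceiling per budget level
    max_source_combos: int = 256


@dataclass
class OracleResult:
    cost: float
    alignment: LabeledAlignment


# column types; per mode only a subset applies
_STAR_COLS = ("match", "mx", "my", "dm", "dmx", "dmy", "la", "dx", "dy")

# run indices in the search state
_LA, _LX, _LY, _DM, _DX, _DY = range(6)
_EMPTY_STATE = (0, 0, 0, (), (), ())

# per column type: runs closed (reset), run extended by a loss, dup run
# extended.  Runs not listed are merely suspended (the column has no cell in
# the genome the run is contiguous in).
_RULES = {
    #         closes                      loss-extends  dup-extends
    "match": ((_LA, _LX, _LY, _DM, _DX, _DY), None, None),
    "mx":    ((_LA, _LX, _DM, _DX), _LY, None),
    "my":    ((_LA, _LY, _DM, _DY), _LX, None),
    "dm":    ((_LX, _LY, _DX, _DY), None, _DM),
    "dmx":   ((_LX, _DX), _LY, _DM),
    "dmy":   ((_LY, _DY), _LX, _DM),
    "la":    ((), _LA, None),
    "dx":    ((), None, _DX),
    "dy":    ((), None, _DY),
    # pair modes
    "ly":    ((_LX, _DX), _LY, None),   # [x,-] kept by the parent, lost in Y
    "lx":    ((_LY, _DY), _LX, None),   # [-,y]
    "pdx":   ((), None, _DX),           # [x,-] duplication in X (sibling)
    "pdy":   ((), None, _DY),
    "dla":   ((_DX,), _LA, None),       # [a,-] loss on a directed branch
    "ddx":   ((), None, _DX),           # [-,x] duplication, directed
    "rev":   ((_LA, _LX, _LY, _DM, _DX, _DY), None, None),
}

_CONSUME = {
    "match": (1, 1, 1), "mx": (1, 1, 0), "my": (1, 0, 1), "dm": (0, 1, 1),
    "dmx": (0, 1, 0), "dmy": (0, 0, 1), "la": (1, 0, 0), "dx": (0, 1, 0),
    "dy": (0, 0, 1),
    # pair modes read only the first two components (row1, row2)
    "ly": (1, 0, 0), "lx": (0, 1, 0), "pdx": (1, 0, 0), "pdy": (0, 1, 0),
    "dla": (1, 0, 0), "ddx": (0, 1, 0), "rev": (1, 1, 1),
}


class _Enumerator:
    def __init__(self, rows: dict[str, Segment], mode: str, costs: CostScheme,
                 budget: OracleBudget):
        self.mode = mode  # "star" | "siblings" | "directed"
        self.rows = rows
        self.costs = costs
        self.budget = budget
        self._check_scheme()
        lens = [len(s) for s in rows.values()]
        if max(lens, default=0) > budget.max_genome_len or \
                sum(lens) > budget.max_total_len:
            raise OracleBudgetError(
                f"instance size {lens} exceeds the oracle budget")
        self.index = SubstringIndex(rows)
        self.signed = has_negative(*rows.values())
        if mode == "star" and self.signed:
            raise ValueError("the exhaustive 3-star solver covers unsigned "
                             "(duplication/loss) instances only")
        if mode == "star":
            self.ids = ("A", "X", "Y")
        elif mode == "directed":
            self.ids = ("A", "X")
        else:
            self.ids = ("X", "Y")
        self.seqs = tuple(rows[i] for i in self.ids)
        self.nodes = 0
        # admissible pruning bound: ancestor genes in excess of all possible
        # match partners must be lost, each costing at least the smallest
        # loss marginal
        ls = [costs.loss(m) for m in range(1, 6)]
        self._min_loss_marg = min([ls[0]] + [b - a for a, b in zip(ls, ls[1:])])
        self._sufcnt = [self._suffix_counts(s) for s in self.seqs]

    @staticmethod
    def _suffix_counts(seq: Segment) -> list[dict]:
        out = [dict() for _ in range(len(seq) + 1)]
        acc: dict = {}
        for p in range(len(seq) - 1, -1, -1):
            acc = dict(acc)
            acc[seq[p]] = acc.get(seq[p], 0) + 1
            out[p] = acc
        return out

    def _lb(self, i: int, j: int, k) -> float:
        if self._min_loss_marg <= 0 or "A" not in self.ids:
            return 0.0
        ca = self._sufcnt[0][i]
        cx = self._sufcnt[1][j]
        cy = self._sufcnt[2][k] if self.mode == "star" else {}
        deficit = 0
        for fam, na in ca.items():
            d = na - cx.get(fam, 0) - cy.get(fam, 0)
            if d > 0:
                deficit += d
        return deficit * self._min_loss_marg

    def _check_scheme(self) -> None:
        c = self.costs
        if len({c.dup(m) for m in (1, 2, 3, 7)}) != 1:
            raise ValueError("oracle requires length-independent duplication "
                             "costs")
        losses = [c.loss(m) for m in range(1, 6)]
        if any(b < a for a, b in zip(losses, losses[1:])):
            raise ValueError("oracle requires non-decreasing loss costs")

    # ------------------------------------------------------------------
    def solve(self) -> OracleResult:
        ub = min(self.budget.max_cost, int(self._upper_bound()) + 1)
        for b in range(0, ub + 1):
            # strict pass: each (prefixes, open-run) state is expanded once,
            # which preserves the existence of a minimum-cost labeling; the
            # lenient pass re-enumerates equal-cost alternatives and is only
            # needed when every strict witness was rejected as cyclic
            for strict in (True, False):
                self.memo: dict = {}
                self.stack: list = []
                found = False
                for cost, trail in self._dfs(*self._start(), _EMPTY_STATE,
                                             0.0, float(b), strict):
                    found = True
                    result = self._witness(trail, cost)
                    if result is not None:
                        return result
                if not found:
                    break  # nothing at this budget; lenient finds none either
        raise OracleInfeasibleError(
            "no feasible labeling found within the cost ceiling")

    def _start(self):
        if self.mode == "star":
            return (0, 0, 0)
        return (0, 0, None)

    def _upper_bound(self) -> float:
        c = self.costs
        n = sum(len(s) for s in self.seqs)
        return c.loss(1) * n + c.dup(1) * n + 1

    # ------------------------------------------------------------------
    def _dfs(self, i, j, k, state, cost, bud,
             strict: bool = True) -> Iterator[tuple[float, tuple]]:
        self.nodes += 1
        if self.nodes > self.budget.max_nodes:
            raise OracleBudgetError("oracle node ceiling exceeded")
        key = (i, j, k, state)
        seen = self.memo.get(key)
        if seen is not None and (cost > seen or (strict and cost >= seen)):
            return
        if seen is None or cost < seen:
            self.memo[key] = cost
        done = self._done(i, j, k)
        if done:
            yield cost, tuple(self.stack)
            return
        for ctype, m, charge, nstate, cut in self._options(i, j, k, state):
            nc = cost + charge
            if nc > bud + 1e-9:
                continue
            di, dj, dk = _CONSUME[ctype]
            if self.mode == "star":
                ni, nj, nk = i + di * m, j + dj * m, k + dk * m
            else:
                ni, nj, nk = i + di * m, j + dj * m, None
            if nc + self._lb(ni, nj, nk) > bud + 1e-9:
                continue
            self.stack.append((ctype, m, cut))
            yield from self._dfs(ni, nj, nk, nstate, nc, bud, strict)
            self.stack.pop()

    def _done(self, i, j, k) -> bool:
        if self.mode == "star":
            return (i, j, k) == tuple(len(s) for s in self.seqs)
        return (i, j) == (len(self.seqs[0]), len(self.seqs[1]))

    # ------------------------------------------------------------------
    def _options(self, i, j, k, state):
        if self.mode == "star":
            yield from self._star_options(i, j, k, state)
        else:
            yield from self._pair_options(i, j, state)

    def _loss_marginal(self, length: int) -> float:
        if length == 0:
            return self.costs.loss(1)
        return self.costs.loss(length + 1) - self.costs.loss(length)

    def _occ_excluding(self, content: Segment, images) -> bool:
        """Does content occur somewhere disjoint from the part's own target
        image?  An event cannot source the very genes it creates."""
        m = len(content)
        for gid, p in self.index.occurrences(content):
            if all(gid != ig or not (max(p, a) < min(p + m, b))
                   for ig, a, b in images):
                return True
        return False

    def _apply(self, ctype: str, state, gene: Optional[Gene],
               poses: Optional[dict[str, int]] = None):
        """All (charge, new state, new-part flag) variants for one column.

        ``poses`` maps row id -> genome position of the gene a duplication
        run consumes, used to grow the open part's target image.
        """
        closes, lext, dext = _RULES[ctype]
        base = list(state)
        for r in closes:
            base[r] = () if r >= _DM else 0
        charge = 0.0
        if lext is not None:
            charge += self._loss_marginal(base[lext])
            base[lext] += 1
        if dext is None:
            yield charge, tuple(base), False
            return
        dup_unit = self.costs.dup(1)
        new_images = tuple(sorted((rid, p, p + 1) for rid, p in poses.items()))
        part = base[dext]
        if part:
            content, images = part
            merged = dict((ig, (a, b)) for ig, a, b in images)
            for rid, p in poses.items():
                a, b = merged.get(rid, (p, p))
                merged[rid] = (min(a, p), max(b, p + 1))
            images2 = tuple(sorted((ig, a, b) for ig, (a, b) in merged.items()))
            content2 = content + (gene,)
            if self._occ_excluding(content2, images2):
                ext = list(base)
                ext[dext] = (content2, images2)
                yield charge, tuple(ext), False
        if self._occ_excluding((gene,), new_images):
            new = list(base)
            new[dext] = ((gene,), new_images)
            yield charge + dup_unit, tuple(new), True

    def _star_options(self, i, j, k, state):
        A, X, Y = self.seqs
        na, nx, ny = len(A), len(X), len(Y)
        cand: list[tuple[str, Optional[Gene], dict]] = []
        if i < na and j < nx and k < ny and A[i] == X[j] == Y[k]:
            cand.append(("match", None, {}))
        if i < na and j < nx and A[i] == X[j]:
            cand.append(("mx", None, {}))
        if i < na and k < ny and A[i] == Y[k]:
            cand.append(("my", None, {}))
        if j < nx and k < ny and X[j] == Y[k]:
            cand.append(("dm", X[j], {"X": j, "Y": k}))
        if j < nx:
            cand.append(("dmx", X[j], {"X": j}))
            cand.append(("dx", X[j], {"X": j}))
        if k < ny:
            cand.append(("dmy", Y[k], {"Y": k}))
            cand.append(("dy", Y[k], {"Y": k}))
        if i < na:
            cand.append(("la", None, {}))
        for ctype, gene, poses in cand:
            for charge, nstate, cut in self._apply(ctype, state, gene, poses):
                yield ctype, 1, charge, nstate, cut

    def _pair_options(self, i, j, state):
        U, V = self.seqs
        fid, sid = self.ids
        nu, nv = len(U), len(V)
        directed = self.mode == "directed"
        cand: list[tuple[str, Optional[Gene], dict]] = []
        if i < nu and j < nv and U[i] == V[j]:
            cand.append(("match", None, {}))
        if directed:
            if i < nu:
                cand.append(("dla", None, {}))
            if j < nv:
                cand.append(("ddx", V[j], {sid: j}))
        else:
            if i < nu:
                cand.append(("ly", None, {}))
                cand.append(("pdx", U[i], {fid: i}))
            if j < nv:
                cand.append(("lx", None, {}))
                cand.append(("pdy", V[j], {sid: j}))
        for ctype, gene, poses in cand:
            for charge, nstate, cut in self._apply(ctype, state, gene, poses):
                yield ctype, 1, charge, nstate, cut
        if self.signed:
            maxm = min(nu - i, nv - j)
            for m in range(1, maxm + 1):
                if tuple(U[i:i + m]) == reverse_of(V[j:j + m]):
                    charge, nstate, _ = next(iter(
                        self._apply("rev", state, None, {})))
                    yield "rev", m, charge + self.costs.rev(m), nstate, False

    # ------------------------------------------------------------------
    # witness construction
    def _witness(self, trail, cost: float) -> Optional[OracleResult]:
        if self.mode == "star":
            rows, events = self._star_events(trail)
        else:
            rows, events = self._pair_events(trail)
        ops = self._assign_sources(rows, events)
        if ops is None:
            return None
        aln = LabeledAlignment(
            rows={rid: tuple(cells) for rid, cells in rows.items()},
            row_order=list(self.ids), ops=ops,
            ancestors=frozenset({"A"}) if "A" in self.ids else frozenset())
        return OracleResult(cost=cost, alignment=aln)

    def _star_events(self, trail):
        A, X, Y = self.seqs
        rows = {"A": [], "X": [], "Y": []}
        i = j = k = 0
        # active events: per run index, dict with chunks [(c1, len)] and for
        # dup runs a list of parts, each a list of chunks plus content
        active: dict[int, dict] = {}
        events: list[dict] = []
        pk = lambda a, b: frozenset((a, b))
        COVERS = {
            _LA: ("M", LOSS, frozenset({pk("A", "X"), pk("A", "Y")})),
            _LX: ("X", LOSS, frozenset({pk("A", "X"), pk("X", "Y")})),
            _LY: ("Y", LOSS, frozenset({pk("A", "Y"), pk("X", "Y")})),
            _DM: ("M", DUP, frozenset({pk("A", "X"), pk("A", "Y")})),
            _DX: ("X", DUP, frozenset({pk("A", "X"), pk("X", "Y")})),
            _DY: ("Y", DUP, frozenset({pk("A", "Y"), pk("X", "Y")})),
        }

        def close(r):
            ev = active.pop(r, None)
            if ev is not None:
                events.append(ev)

        def extend(r, col, gene, cut, poses):
            branch, kind, covers = COVERS[r]
            if r not in active:
                active[r] = {"run": r, "branch": branch, "kind": kind,
                             "covers": covers, "parts": []}
            ev = active[r]
            if kind == LOSS:
                parts = ev["parts"]
                if not parts:
                    parts.append({"chunks": [], "content": [], "images": {}})
                part = parts[0]
            else:
                if cut or not ev["parts"]:
                    ev["parts"].append({"chunks": [], "content": [],
                                        "images": {}})
                part = ev["parts"][-1]
            chunks = part["chunks"]
            if chunks and chunks[-1][0] + chunks[-1][1] == col:
                chunks[-1] = (chunks[-1][0], chunks[-1][1] + 1)
            else:
                chunks.append((col, 1))
            if gene is not None:
                part["content"].append(gene)
            for rid, p in poses.items():
                a0, b0 = part["images"].get(rid, (p, p))
                part["images"][rid] = (min(a0, p), max(b0, p + 1))

        for col, (ctype, m, cut) in enumerate(trail):
            closes, lext, dext = _RULES[ctype]
            for r in closes:
                close(r)
            a = A[i] if _CONSUME[ctype][0] else None
            x = X[j] if _CONSUME[ctype][1] else None
            y = Y[k] if _CONSUME[ctype][2] else None
            rows["A"].append(a)
            rows["X"].append(x)
            rows["Y"].append(y)
            poses = {}
            if dext is not None:
                if x is not None:
                    poses["X"] = j
                if y is not None:
                    poses["Y"] = k
            if lext is not None:
                extend(lext, col, None, False, {})
            if dext is not None:
                extend(dext, col, x if x is not None else y, cut, poses)
            i, j, k = i + (a is not None), j + (x is not None), k + (y is not None)
        for r in list(active):
            close(r)
        return rows, events

    def _pair_events(self, trail):
        U, V = self.seqs
        fid, sid = self.ids
        rows = {fid: [], sid: []}
        i = j = 0
        active: dict[int, dict] = {}
        events: list[dict] = []
        pair = frozenset({frozenset((fid, sid))})
        COVERS = {
            _LA: (sid, LOSS, pair), _LX: (fid, LOSS, pair),
            _LY: (sid, LOSS, pair),
            _DX: (fid if self.mode == "siblings" else sid, DUP, pair),
            _DY: (sid, DUP, pair),
        }

        def close(r):
            ev = active.pop(r, None)
            if ev is not None:
                events.append(ev)

        def extend(r, col, gene, cut, poses):
            branch, kind, covers = COVERS[r]
            if r not in active:
                active[r] = {"run": r, "branch": branch, "kind": kind,
                             "covers": covers, "parts": []}
            ev = active[r]
            if kind == LOSS:
                if not ev["parts"]:
                    ev["parts"].append({"chunks": [], "content": [], "images": {}})
                part = ev["parts"][0]
            else:
                if cut or not ev["parts"]:
                    ev["parts"].append({"chunks": [], "content": [], "images": {}})
                part = ev["parts"][-1]
            chunks = part["chunks"]
            if chunks and chunks[-1][0] + chunks[-1][1] == col:
                chunks[-1] = (chunks[-1][0], chunks[-1][1] + 1)
            else:
                chunks.append((col, 1))
            if gene is not None:
                part["content"].append(gene)
            for rid, p in poses.items():
                a0, b0 = part["images"].get(rid, (p, p))
                part["images"][rid] = (min(a0, p), max(b0, p + 1))

        col = 0
        for ctype, m, cut in trail:
            closes, lext, dext = _RULES[ctype]
            for r in closes:
                close(r)
            for t in range(m):
                du, dv, _ = _CONSUME[ctype]
                u = U[i] if du else None
                v = V[j] if dv else None
                rows[fid].append(u)
                rows[sid].append(v)
                if ctype == "rev":
                    pass  # handled below as a block op
                else:
                    poses = {}
                    if dext is not None:
                        if u is not None:
                            poses[fid] = i
                        if v is not None:
                            poses[sid] = j
                    if lext is not None:
                        extend(lext, col, None, False, {})
                    if dext is not None:
                        extend(dext, col, u if u is not None else v,
                               cut if t == 0 else False, poses)
                i, j = i + (u is not None), j + (v is not None)
                col += 1
            if ctype == "rev":
                events.append({"run": None, "branch": sid, "kind": REV,
                               "covers": pair,
                               "parts": [{"chunks": [(col - m, m)],
                                          "content": []}]})
        for r in list(active):
            close(r)
        return rows, events

    # ------------------------------------------------------------------
    def _assign_sources(self, rows, events) -> Optional[list[AlignOp]]:
        """Emit AlignOps, choosing duplication sources so that no cycle of
        leaf-internal duplications remains; None when impossible."""
        leaf_rows = [r for r in self.ids if r != "A"]
        col2pos = {rid: self._col_to_pos(rows[rid]) for rid in rows}

        fixed_ops: list[AlignOp] = []
        dup_chunks = []  # (event, chunk cols, content, candidates)
        target_regions: dict[str, list[tuple[int, int]]] = {r: [] for r in rows}
        for ev in events:
            for part in ev["parts"]:
                for (c1, ln) in part["chunks"]:
                    if ev["kind"] == DUP and ev["branch"] in leaf_rows:
                        row = ev["branch"]
                        p1 = col2pos[row][c1]
                        target_regions[row].append((p1, p1 + ln))

        for ev in events:
            for part in ev["parts"]:
                off = 0
                for (c1, ln) in part["chunks"]:
                    cols = (c1, c1 + ln)
                    if ev["kind"] != DUP:
                        fixed_ops.append(AlignOp(ev["kind"], cols, ev["branch"],
                                                 ev["covers"]))
                        continue
                    content = tuple(part["content"][off:off + ln])
                    off += ln
                    row = ev["branch"] if ev["branch"] in leaf_rows else None
                    tpos = None
                    if row is not None:
                        p1 = col2pos[row][c1]
                        tpos = (row, (p1, p1 + ln))
                    # an event cannot source from its own target image
                    images = [(rid, iv) for rid, iv in part["images"].items()]
                    cands = self._source_candidates(content, tpos,
                                                    target_regions, images)
                    if not cands:
                        return None
                    dup_chunks.append((ev, cols, content, cands, tpos))

        # try source combinations until the leaf-dup overlap digraph is acyclic
        option_lists = [c[3] for c in dup_chunks]
        combos = itertools.islice(itertools.product(*option_lists),
                                  self.budget.max_source_combos)
        for combo in combos:
            ops = list(fixed_ops)
            checkable = []
            ok = True
            for (ev, cols, content, _, tpos), src in zip(dup_chunks, combo):
                ops.append(AlignOp(DUP, cols, ev["branch"], ev["covers"], src))
                if tpos is not None and src[0] in leaf_rows:
                    checkable.append((tpos, src))
            if checkable and self._has_cycle(checkable):
                ok = False
            if ok:
                return ops
        return None

    def _source_candidates(self, content, tpos, target_regions, images=()):
        """Occurrences ordered safest-first: ancestral genome, then leaf
        positions outside every duplication target, then the rest."""
        occ = self.index.occurrences(content)
        safe, neutral, risky = [], [], []
        for gid, p in occ:
            iv = (gid, (p, p + len(content)))
            if tpos is not None and iv == tpos:
                continue  # the target itself is not a source
            if any(gid == ig and max(p, a) < min(p + len(content), b)
                   for ig, (a, b) in images):
                continue  # a center duplication's own leaf image
            if gid == "A":
                safe.append(iv)
            elif all(not (max(p, a) < min(p + len(content), b))
                     for a, b in target_regions.get(gid, [])):
                neutral.append(iv)
            else:
                risky.append(iv)
        if safe:
            return [safe[0]]
        if neutral:
            return [neutral[0]]
        return risky

    @staticmethod
    def _has_cycle(checkable) -> bool:
        n = len(checkable)
        adj = [[] for _ in range(n)]
        for p in range(n):
            (tg, (t1, t2)), _ = checkable[p]
            for q in range(n):
                (sg_t, _), (sg, (s1, s2)) = checkable[q][0], checkable[q][1]
                if tg == sg and max(t1, s1) < min(t2, s2):
                    adj[p].append(q)
        WHITE, GREY, BLACK = 0, 1, 2
        color = [WHITE] * n
        for start in range(n):
            if color[start] != WHITE:
                continue
            stack = [(start, iter(adj[start]))]
            color[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == GREY:
                        return True
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(adj[nxt])))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
        return False

    @staticmethod
    def _col_to_pos(cells) -> dict[int, int]:
        out, p = {}, 0
        for c, g in enumerate(cells):
            if g is not None:
                out[c] = p
                p += 1
        return out


# ---------------------------------------------------------------------------
# public API

def exact_pair_cost(X: GeneOrder, Y: GeneOrder,
                    costs: Optional[CostScheme] = None, mode: str = "siblings",
                    budget: Optional[OracleBudget] = None) -> OracleResult:
    """Optimal pairwise labeled-alignment cost with a feasibility witness.

    ``siblings`` treats the rows as a cherry below a free parent;
    ``directed`` treats the first row as the ancestor of the second.
    """
    if mode not in ("siblings", "directed"):
        raise ValueError(f"unknown mode {mode!r}")
    costs = costs or CostScheme.unit()
    budget = budget or OracleBudget()
    ids = ("A", "X") if mode == "directed" else ("X", "Y")
    rows = {ids[0]: tuple(X.genes), ids[1]: tuple(Y.genes)}
    return _Enumerator(rows, mode, costs, budget).solve()


def exact_star_cost(A: GeneOrder, X: GeneOrder, Y: GeneOrder,
                    costs: Optional[CostScheme] = None,
                    budget: Optional[OracleBudget] = None) -> OracleResult:
    """Optimal 3-star cost (duplication + loss model) with a witness."""
    costs = costs or CostScheme.unit()
    budget = budget or OracleBudget()
    rows = {"A": tuple(A.genes), "X": tuple(X.genes), "Y": tuple(Y.genes)}
    return _Enumerator(rows, "star", costs, budget).solve()
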