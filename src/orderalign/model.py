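"""Core domain model for gene-order evolution.

A genome is abstracted as a *gene order*: a string of signed symbols over an
alphabet of gene families, where repeated symbols are paralogs and the sign is
the transcriptional orientation.  Evolution acts on gene orders through three
operations:

* **duplication** ``D(k)`` — copy a length-``k`` substring (the *source*) to a
  new location (the *target*) outside the source interval; when source and
  target lie in different genomes this doubles as a transposition surrogate;
* **loss** ``L(k)`` — delete a length-``k`` substring (empty target);
* **reversal** ``R(k)`` — replace a substring by its reverse: order flipped
  and every sign negated.

A *history* is an ordered sequence of operations along one branch of a
phylogeny; replaying it on the ancestor must reproduce the descendant.

A *labeled alignment* is a gap-padded alignment of two or more gene orders
together with a set of operations that explains every non-match column pair:
matches are covered by no operation, mismatches by exactly one reversal, and
gap pairs by exactly one non-reversal operation.  When one row is ancestral to
another, operations may only flow away from the ancestor.

All intervals are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, NamedTuple, Optional, Sequence

GAP = None  # gap cell in an alignment row

DUP = "duplication"
LOSS = "loss"
REV = "reversal"


class Gene(NamedTuple):
    """A signed gene-family symbol.  ``sign`` is +1 or -1."""

    family: str
    sign: int = 1

    def __neg__(self) -> "Gene":
        return Gene(self.family, -self.sign)

    @classmethod
    def from_token(cls, token: str) -> "Gene":
        """Parse a text token: a leading '-' marks negative orientation."""
        token = token.strip()
        if not token:
            raise ValueError("empty gene token")
        if token.startswith("-"):
            if len(token) == 1:
                raise ValueError("bare '-' is not a gene token")
            return cls(token[1:], -1)
        return cls(token, 1)

    def token(self) -> str:
        return self.family if self.sign >= 0 else "-" + self.family


Segment = tuple[Gene, ...]


def reverse_of(segment: Sequence[Gene]) -> Segment:
    """Order-reverse a segment and flip every sign (an involution)."""
    return tuple(Gene(g.family, -g.sign) for g in reversed(segment))


@dataclass(frozen=True)
class GeneOrder:
    """A genome (or internal-node assignment): a finite sequence of genes."""

    genes: Segment = ()
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, idx):
        return self.genes[idx]

    def same_content(self, other: "GeneOrder") -> bool:
        return self.genes == other.genes

    def with_id(self, id: str) -> "GeneOrder":
        return replace(self, id=id)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str], id: str = "") -> "GeneOrder":
        return cls(tuple(Gene.from_token(t) for t in tokens), id)

    @classmethod
    def from_string(cls, text: str, id: str = "") -> "GeneOrder":
        """Compact constructor: one character per gene, '-' negating the next.

        ``from_string("ab-c")`` is the order ``+a +b -c``.  Convenient for
        small examples and tests; file I/O uses whitespace-separated tokens.
        """
        genes: list[Gene] = []
        sign = 1
        for ch in text:
            if ch == "-":
                sign = -1
            elif ch.isspace():
                continue
            else:
                genes.append(Gene(ch, sign))
                sign = 1
        return cls(tuple(genes), id)

    def tokens(self) -> list[str]:
        return [g.token() for g in self.genes]

    def __str__(self) -> str:
        return " ".join(self.tokens())


@dataclass(frozen=True)
class CostScheme:
    """Cost functions per operation kind, each mapping length -> cost >= 0.

    The package default charges one per event regardless of length.  The
    duplication/single-gene-loss model used in the accuracy experiments is
    expressed as ``c_L(k) = k`` (a length-k deletion counts as k single-gene
    losses) with unit duplications.
    """

    dup: Callable[[int], float] = lambda k: 1.0
    loss: Callable[[int], float] = lambda k: 1.0
    rev: Callable[[int], float] = lambda k: 1.0
    name: str = "unit"

    def cost(self, kind: str, length: int) -> float:
        if length <= 0:
            raise ValueError("operation length must be positive")
        c = {DUP: self.dup, LOSS: self.loss, REV: self.rev}[kind](length)
        if c < 0:
            raise ValueError("negative operation cost")
        return c

    @classmethod
    def unit(cls) -> "CostScheme":
        return cls()

    @classmethod
    def dup_singleloss(cls) -> "CostScheme":
        """Duplications + single-gene losses, one unit per event."""
        return cls(dup=lambda k: 1.0, loss=lambda k: float(k),
                   rev=lambda k: 1.0, name="dup_singleloss")


def occurs_in(pattern: Sequence[Gene], text: GeneOrder | Sequence[Gene],
              mode: str = "forward") -> bool:
    """Signed-exact substring test.

    ``forward`` looks for the pattern in the text as written;
    ``forward_or_reverse`` also accepts an occurrence in the reverse of the
    text (off by default: inverted duplications are outside the model).
    """
    pat = tuple(pattern)
    if not pat:
        raise ValueError("empty pattern")
    seq = tuple(text.genes if isinstance(text, GeneOrder) else text)
    if _find(pat, seq):
        return True
    if mode == "forward_or_reverse":
        return bool(_find(pat, reverse_of(seq)))
    if mode != "forward":
        raise ValueError(f"unknown mode {mode!r}")
    return False


def _find(pat: Segment, seq: Segment) -> list[int]:
    n, m = len(seq), len(pat)
    return [i for i in range(n - m + 1) if seq[i:i + m] == pat]


@dataclass(frozen=True)
class Operation:
    """A typed evolutionary event in genome coordinates.

    ``source``/``target`` are ``(genome_id, (start, end))`` pairs.  A loss has
    no target.  A duplication whose source lies in another observed genome
    (the transposition reading) carries its inserted ``content`` explicitly so
    that a branch history stays replayable on its own.
    """

    kind: str
    length: int
    source: tuple[str, tuple[int, int]]
    target: Optional[tuple[str, tuple[int, int]]] = None
    content: Optional[Segment] = None

    def __post_init__(self) -> None:
        if self.kind not in (DUP, LOSS, REV):
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("operation length must be >= 1")
        if self.kind == LOSS and self.target is not None:
            raise ValueError("loss must have an empty target")
        if self.kind != LOSS and self.target is None:
            raise ValueError(f"{self.kind} requires a target")
        if self.kind == REV:
            sg, si = self.source
            tg, ti = self.target
            if sg != tg or si != ti:
                raise ValueError("reversal source and target must coincide")


History = list[Operation]


def replay_history(start: GeneOrder, history: Sequence[Operation]) -> GeneOrder:
    """Apply a branch history left-to-right to a gene order.

    Duplication inserts a copy of the source substring at the target start
    (content taken from the evolving genome when the source genome matches,
    from ``op.content`` otherwise); loss deletes the source substring;
    reversal replaces the source substring in place by its reverse.
    """
    seq = list(start.genes)
    for op in history:
        if op.kind == LOSS:
            s1, s2 = op.source[1]
            _check_range(s1, s2, len(seq), op)
            del seq[s1:s2]
        elif op.kind == REV:
            s1, s2 = op.source[1]
            _check_range(s1, s2, len(seq), op)
            seq[s1:s2] = reverse_of(seq[s1:s2])
        else:  # duplication
            t1, t2 = op.target[1]
            if not (0 <= t1 <= len(seq)):
                raise ValueError(f"duplication target out of range: {op}")
            if op.content is not None:
                # recorded content is authoritative: the source interval may
                # refer to an observed genome rather than the evolving one
                piece = tuple(op.content)
            elif op.source[0] == start.id or not op.source[0]:
                s1, s2 = op.source[1]
                _check_range(s1, s2, len(seq), op)
                piece = tuple(seq[s1:s2])
            else:
                raise ValueError(
                    f"cross-genome duplication requires content: {op}")
            if len(piece) != op.length:
                raise ValueError(f"duplication length mismatch: {op}")
            seq[t1:t1] = piece
    return GeneOrder(tuple(seq), start.id)


def _check_range(s1: int, s2: int, n: int, op: Operation) -> None:
    if not (0 <= s1 < s2 <= n):
        raise ValueError(f"operation interval [{s1},{s2}) out of range 0..{n}: {op}")


@dataclass(frozen=True)
class AlignOp:
    """An operation in alignment-column coordinates.

    ``cols`` is the half-open column interval the operation writes (the
    duplication target, the reversed block, or the lost segment).  ``branch``
    names the tree edge the event sits on by the id of the node the edge leads
    to (for a 3-star ``A|XY`` with center ``M``: "M" for the A->M edge, "X"
    and "Y" for the edges below the center).  ``covers`` lists the unordered
    row pairs whose non-match cells this operation explains.  ``source`` is a
    genome-coordinate occurrence for duplications.
    """

    kind: str
    cols: tuple[int, int]
    branch: str
    covers: frozenset[frozenset[str]]
    source: Optional[tuple[str, tuple[int, int]]] = None

    @property
    def length(self) -> int:
        return self.cols[1] - self.cols[0]


def _pairkey(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclass
class LabeledAlignment:
    """Gap-padded rows of equal length plus a labeling of all non-match cells.

    ``rows`` maps row id -> tuple over genes and gaps (``None``);
    ``row_order`` fixes presentation order; ``ancestors`` flags rows that are
    ancestral to every other row (no operation may target them).
    """

    rows: dict[str, tuple[Optional[Gene], ...]]
    row_order: list[str]
    ops: list[AlignOp] = field(default_factory=list)
    ancestors: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, row_id: str) -> GeneOrder:
        return GeneOrder(tuple(g for g in self.rows[row_id] if g is not None),
                         row_id)

    def column(self, c: int) -> dict[str, Optional[Gene]]:
        return {rid: self.rows[rid][c] for rid in self.row_order}

    def col_to_pos(self, row_id: str) -> dict[int, int]:
        """Map alignment column -> genome position for non-gap cells."""
        out: dict[int, int] = {}
        p = 0
        for c, g in enumerate(self.rows[row_id]):
            if g is not None:
                out[c] = p
                p += 1
        return out


def labeling_cost(alignment: LabeledAlignment, costs: CostScheme) -> float:
    """Sum of per-event costs of the labeling."""
    total = 0.0
    lam = alignment.length
    for op in alignment.ops:
        c1, c2 = op.cols
        if not (0 <= c1 < c2 <= lam):
            raise ValueError(f"operation columns [{c1},{c2}) outside alignment "
                             f"of length {lam}")
        total += costs.cost(op.kind, op.length)
    return total


def validate_alignment(alignment: LabeledAlignment) -> list[str]:
    """Check the labeled-alignment contract; return a list of violations.

    Clauses checked: equal row lengths; no all-gap column; every match pair
    covered by no operation; every mismatch pair covered by exactly one
    reversal; every gap pair covered by exactly one non-reversal operation;
    no operation on a branch named after an ancestral row; duplication target
    content equals its recorded source content.
    """
    issues: list[str] = []
    lam = alignment.length
    for rid in alignment.row_order:
        if len(alignment.rows[rid]) != lam:
            issues.append(f"row {rid} has length {len(alignment.rows[rid])} != {lam}")
            return issues
    for c in range(lam):
        if all(alignment.rows[rid][c] is None for rid in alignment.row_order):
            issues.append(f"column {c} is all gaps")

    # ops covering each (pair, column)
    cover: dict[tuple[frozenset[str], int], list[AlignOp]] = {}
    for op in alignment.ops:
        if op.branch in alignment.ancestors:
            issues.append(f"operation targets ancestral row via branch {op.branch}: {op}")
        for c in range(*op.cols):
            for pair in op.covers:
                cover.setdefault((pair, c), []).append(op)

    ids = alignment.row_order
    for i, l in enumerate(ids):
        for m in ids[i + 1:]:
            pair = _pairkey(l, m)
            for c in range(lam):
                gl, gm = alignment.rows[l][c], alignment.rows[m][c]
                if gl is None and gm is None:
                    continue
                here = cover.get((pair, c), [])
                if gl is not None and gm is not None:
                    if gl == gm:
                        if here:
                            issues.append(f"match ({l},{m}) col {c} is covered")
                    else:
                        revs = [o for o in here if o.kind == REV]
                        if len(revs) != 1 or len(here) != 1:
                            issues.append(
                                f"mismatch ({l},{m}) col {c} needs exactly one "
                                f"reversal, found {len(here)} op(s)")
                else:
                    nonrev = [o for o in here if o.kind != REV]
                    if len(here) != 1 or len(nonrev) != 1:
                        issues.append(
                            f"gap pair ({l},{m}) col {c} needs exactly one "
                            f"non-reversal op, found {len(here)}")

    issues.extend(_check_dup_sources(alignment))
    return issues


def _check_dup_sources(alignment: LabeledAlignment) -> list[str]:
    issues = []
    for op in alignment.ops:
        if op.kind != DUP or op.source is None:
            continue
        gid, (s1, s2) = op.source
        if gid not in alignment.rows:
            continue  # source in a genome not part of this alignment view
        src = alignment.ungapped(gid).genes
        if not (0 <= s1 < s2 <= len(src)):
            issues.append(f"duplication source interval out of range: {op}")
            continue
        # target content: the non-gap cells of some covered row at op.cols.
        for pair in op.covers:
            for rid in pair:
                cells = [alignment.rows[rid][c] for c in range(*op.cols)]
                genes = tuple(g for g in cells if g is not None)
                if len(genes) == op.length and genes != src[s1:s2] and \
                        genes != reverse_of(src[s1:s2]):
                    issues.append(
                        f"duplication content mismatch on row {rid}: {op}")
    return issues


@dataclass(frozen=True)
class StarInstance:
    """A 3-star ``A|XY``: grandparent assignment A above siblings X and Y.

    A is ancestral: no operation in any labeling of the instance may target
    the A row.  Solving the instance chooses the center genome M and three
    branch histories ``A->M``, ``M->X``, ``M->Y`` of minimum total cost.
    """

    A: GeneOrder
    X: GeneOrder
    Y: GeneOrder
    costs: CostScheme = field(default_factory=CostScheme.unit)

    def __post_init__(self) -> None:
        for name in ("A", "X", "Y"):
            go = getattr(self, name)
            if go.id != name:
                object.__setattr__(self, name, go.with_id(name))

    def unreachable_cost(self) -> float:
        """A finite sentinel strictly above any achievable labeling cost."""
        n = len(self.A) + len(self.X) + len(self.Y)
        per = max(self.costs.cost(k, j) for k in (DUP, LOSS, REV)
                  for j in (1, max(1, n)))
        return 1.0 + per * (2 * n + 2)
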