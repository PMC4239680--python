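"""Shared condition tables for the alignment dynamic programs.

Both the 3-star and the pairwise DP repeatedly ask the same questions about
prefix suffixes: how long a common suffix two prefixes share, how long a
suffix of a prefix still occurs somewhere as a substring, and which suffix
lengths satisfy a reversal condition.  These are precomputed here once per
instance.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .model import Gene, Segment, reverse_of


def lcs_suffix_table(u: Sequence[Gene], v: Sequence[Gene]) -> list[list[int]]:
    """T[i][j] = length of the longest common suffix of u[:i] and v[:j]."""
    nu, nv = len(u), len(v)
    t = [[0] * (nv + 1) for _ in range(nu + 1)]
    for i in range(1, nu + 1):
        ui = u[i - 1]
        row = t[i]
        prev = t[i - 1]
        for j in range(1, nv + 1):
            if ui == v[j - 1]:
                row[j] = prev[j - 1] + 1
    return t


class SubstringIndex:
    """Occurrence positions of every substring of a set of genomes."""

    def __init__(self, genomes: dict[str, Segment]):
        self.genomes = genomes
        self._pos: dict[Segment, list[tuple[str, int]]] = {}
        for gid, seq in genomes.items():
            n = len(seq)
            for a in range(n):
                for b in range(a + 1, n + 1):
                    self._pos.setdefault(tuple(seq[a:b]), []).append((gid, a))

    def occurrences(self, seg: Sequence[Gene]) -> list[tuple[str, int]]:
        return self._pos.get(tuple(seg), [])

    def occurs(self, seg: Sequence[Gene], genome_ids: Sequence[str],
               exclude: Optional[tuple[str, int]] = None) -> bool:
        for gid, p in self.occurrences(seg):
            if gid in genome_ids and (gid, p) != exclude:
                return True
        return False

    def max_suffix_occurrence(self, seq: Sequence[Gene], genome_ids: Sequence[str],
                              self_id: Optional[str] = None) -> list[int]:
        """out[j] = max m such that seq[j-m:j] occurs in the listed genomes.

        When ``self_id`` is given and equals the genome ``seq`` was taken
        from, an occurrence of seq[j-m:j] at start j-m of that genome is not
        counted (a duplication may not source itself from its own target).
        The valid-m set is downward closed, so the maximum characterizes it.
        """
        n = len(seq)
        out = [0] * (n + 1)
        for j in range(1, n + 1):
            m = 0
            while m < j:
                seg = tuple(seq[j - m - 1:j])
                exclude = (self_id, j - m - 1) if self_id is not None else None
                if not self.occurs(seg, genome_ids, exclude=exclude):
                    break
                m += 1
            out[j] = m
        return out


def reversal_extensions(u: Sequence[Gene], iend: int,
                        v: Sequence[Gene], jend: int,
                        maxm: int) -> list[int]:
    """All m in 1..maxm with u[iend-m:iend] == reverse_of(v[jend-m:jend]).

    Growing m shifts every pairing, so each length is checked from scratch;
    a sign precheck makes the scan cheap on unsigned data.
    """
    out = []
    for m in range(1, maxm + 1):
        useg = tuple(u[iend - m:iend])
        if useg == reverse_of(v[jend - m:jend]):
            out.append(m)
    return out


def has_negative(*seqs: Sequence[Gene]) -> bool:
    return any(g.sign < 0 for seq in seqs for g in seq)
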