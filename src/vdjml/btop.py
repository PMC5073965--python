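"""BLAST trace-back operations (BTOP) strings: parsing, expansion, statistics.

A BTOP string is a run-length encoding of a pairwise nucleotide alignment
used by BLAST-family tools (including IgBLAST). Its grammar, per the NCBI
convention, is a concatenation of:

* a digit run — that many identical aligned columns (a match run);
* a two-character pair ``XY`` — one aligned column where the read (query)
  shows ``X`` and the germline (subject) shows ``Y``.  A ``-`` on the
  germline side (``C-``) is an insertion in the read; a ``-`` on the read
  side (``-T``) is a deletion from the read.  ``--`` is not a legal column.

From a parsed BTOP the full gapped alignment and the per-segment mutation
statistics (substitutions, insertions, deletions, percent identity) are
recovered without storing the germline sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .model import AnnotationFlags

__all__ = [
    "MatchRun",
    "Mismatch",
    "ReadInsertion",
    "ReadDeletion",
    "BtopOps",
    "BtopError",
    "parse_btop",
    "serialize_btop",
    "summarize",
    "expand",
    "stats_to_flags",
    "AlignmentStats",
]

#: Characters legal on either side of a BTOP pair (IUPAC nucleotide codes,
#: N, or the gap marker).
_PAIR_CHARS = set("ACGTUNRYSWKMBDHV-")


class BtopError(ValueError):
    """Malformed BTOP text; ``offset`` is the 0-based position of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class MatchRun:
    length: int


@dataclass(frozen=True)
class Mismatch:
    read_base: str
    gl_base: str


@dataclass(frozen=True)
class ReadInsertion:
    """A read base aligned to a gap in the germline."""

    read_base: str


@dataclass(frozen=True)
class ReadDeletion:
    """A germline base aligned to a gap in the read."""

    gl_base: str


Op = Union[MatchRun, Mismatch, ReadInsertion, ReadDeletion]


@dataclass(frozen=True)
class BtopOps:
    """A tokenized BTOP string."""

    ops: tuple[Op, ...]

    @property
    def read_span(self) -> int:
        """Number of read positions consumed by the alignment."""
        n = 0
        for op in self.ops:
            if isinstance(op, MatchRun):
                n += op.length
            elif isinstance(op, (Mismatch, ReadInsertion)):
                n += 1
        return n

    @property
    def gl_span(self) -> int:
        """Number of germline positions consumed by the alignment."""
        n = 0
        for op in self.ops:
            if isinstance(op, MatchRun):
                n += op.length
            elif isinstance(op, (Mismatch, ReadDeletion)):
                n += 1
        return n


@dataclass(frozen=True)
class AlignmentStats:
    """Column counts derived from a BTOP.

    ``identity`` is ``100 * matches / columns`` where columns include gap
    columns — the common BLAST reporting convention.
    """

    matches: int
    substitutions: int
    insertions: int
    deletions: int
    read_span: int
    gl_span: int

    @property
    def identity(self) -> float:
        total = self.matches + self.substitutions + self.insertions + self.deletions
        return 100.0 * self.matches / total if total else 0.0


def parse_btop(text: str) -> BtopOps:
    """Tokenize a BTOP string.

    Adjacent digit runs are merged so that ``serialize_btop(parse_btop(s))``
    reproduces any canonical input exactly.  Lowercase bases are accepted
    and uppercased.

    Raises
    ------
    BtopError
        On a dangling single letter, an illegal character, or a ``--`` pair.
    """
    ops: list[Op] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            length = int(text[i:j])
            if length == 0:
                raise BtopError("zero-length match run", i)
            if ops and isinstance(ops[-1], MatchRun):
                ops[-1] = MatchRun(ops[-1].length + length)
            else:
                ops.append(MatchRun(length))
            i = j
            continue
        a = ch.upper()
        if a not in _PAIR_CHARS:
            raise BtopError(f"illegal character {ch!r}", i)
        if i + 1 >= n:
            raise BtopError(f"dangling character {ch!r}", i)
        b = text[i + 1].upper()
        if b not in _PAIR_CHARS or b.isdigit():
            raise BtopError(f"illegal pair character {text[i + 1]!r}", i + 1)
        if a == "-" and b == "-":
            raise BtopError("'--' is not a legal BTOP column", i)
        if a == "-":
            ops.append(ReadDeletion(b))
        elif b == "-":
            ops.append(ReadInsertion(a))
        else:
            ops.append(Mismatch(a, b))
        i += 2
    return BtopOps(tuple(ops))


def serialize_btop(ops: BtopOps) -> str:
    """Render ops back to BTOP text (canonical: merged digit runs).

    Adjacent MatchRun ops are merged before rendering — two digit runs in
    a row would otherwise concatenate into a different number.
    """
    parts: list[str] = []
    for op in ops.ops:
        if isinstance(op, MatchRun):
            if parts and parts[-1].isdigit():
                parts[-1] = str(int(parts[-1]) + op.length)
                continue
            parts.append(str(op.length))
        elif isinstance(op, Mismatch):
            parts.append(op.read_base + op.gl_base)
        elif isinstance(op, ReadInsertion):
            parts.append(op.read_base + "-")
        else:
            parts.append("-" + op.gl_base)
    return "".join(parts)


def summarize(ops: BtopOps) -> AlignmentStats:
    """Count matches, substitutions and indels in a parsed BTOP."""
    matches = subs = ins = dels = 0
    for op in ops.ops:
        if isinstance(op, MatchRun):
            matches += op.length
        elif isinstance(op, Mismatch):
            subs += 1
        elif isinstance(op, ReadInsertion):
            ins += 1
        else:
            dels += 1
    return AlignmentStats(
        matches=matches,
        substitutions=subs,
        insertions=ins,
        deletions=dels,
        read_span=matches + subs + ins,
        gl_span=matches + subs + dels,
    )


def expand(read_subseq: str, ops: BtopOps) -> tuple[str, str]:
    """Reconstruct the gapped alignment from the aligned read subsequence.

    Match columns copy the read base to the germline row; mismatch and gap
    columns take their bases from the ops.  The read bases recorded in the
    BTOP must agree with ``read_subseq``.

    Returns
    -------
    (gapped_read, gapped_germline), equal-length strings.
    """
    if len(read_subseq) != ops.read_span:
        raise ValueError(
            f"read subsequence length {len(read_subseq)} != BTOP read span {ops.read_span}"
        )
    read_subseq = read_subseq.upper()
    gr: list[str] = []
    gg: list[str] = []
    pos = 0
    for op in ops.ops:
        if isinstance(op, MatchRun):
            chunk = read_subseq[pos : pos + op.length]
            gr.append(chunk)
            gg.append(chunk)
            pos += op.length
        elif isinstance(op, Mismatch):
            if read_subseq[pos] != op.read_base:
                raise ValueError(
                    f"read base conflict at read offset {pos}: "
                    f"sequence has {read_subseq[pos]}, BTOP has {op.read_base}"
                )
            gr.append(op.read_base)
            gg.append(op.gl_base)
            pos += 1
        elif isinstance(op, ReadInsertion):
            if read_subseq[pos] != op.read_base:
                raise ValueError(
                    f"read base conflict at read offset {pos}: "
                    f"sequence has {read_subseq[pos]}, BTOP has {op.read_base}"
                )
            gr.append(op.read_base)
            gg.append("-")
            pos += 1
        else:
            gr.append("-")
            gg.append(op.gl_base)
    return "".join(gr), "".join(gg)


def stats_to_flags(
    stats: AlignmentStats, frame_known: Optional[object] = None
) -> AnnotationFlags:
    """Derive per-segment-match annotation flags from alignment statistics.

    ``out_frame_indel`` is true iff the net indel length is not a multiple
    of three, i.e. the indels shift the reading frame.
    """
    return AnnotationFlags(
        identity=round(stats.identity, 1),
        insertions=stats.insertions,
        deletions=stats.deletions,
        substitutions=stats.substitutions,
        out_frame_indel=(stats.insertions - stats.deletions) % 3 != 0,
    )
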