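"""Convert IgBLAST tabular output ("outfmt 7" with a BTOP column) to VDJML.

IgBLAST writes one comment-delimited block per query: a rearrangement
summary (top V/D/J gene matches, chain type, stop codon, V-J frame,
productivity, strand), junction details, a per-region alignment summary
(FR1..FR3, CDR1..CDR2), and a hit table whose rows carry the standard
BLAST tabular columns plus the trace-back-operations (BTOP) string.

Conversion semantics:

* hits with identical alignments — same segment type, read interval,
  BTOP and bit score — collapse into a single segment match listing one
  germline segment entry per gene name;
* the combination is the highest-scoring match of each type present
  (first listed on ties), ordered V, D, J;
* regions come from the alignment summary (converted to 0-based
  coordinates) plus junction regions computed between adjacent segment
  matches of the combination;
* the mutation statistics attached to each segment match (substitutions,
  insertions, deletions, identity, frame-shift flag) are recomputed from
  the BTOP rather than copied from the printed columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

from . import btop as _btop
from .model import (
    Aligner,
    Alignment,
    AnnotationFlags,
    Combination,
    Document,
    Generator,
    GermlineDb,
    GlSegMatch,
    Meta,
    Read,
    Region,
    SegmentMatch,
)

__all__ = [
    "HitRow",
    "RegionRow",
    "IgBlastRecord",
    "IgBlastParseError",
    "parse_igblast_stream",
    "group_hits",
    "select_combination",
    "map_regions",
    "summary_to_flags",
    "convert",
]


class IgBlastParseError(ValueError):
    """Unparseable IgBLAST tabular content; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class HitRow:
    """One row of the IgBLAST hit table (1-based inclusive coordinates)."""

    segment_type: str
    subject_name: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    btop: str


@dataclass(frozen=True)
class RegionRow:
    """One alignment-summary row (1-based inclusive from/to)."""

    name: str
    start: int  # "from"
    end: int  # "to"
    length: int
    matches: int
    mismatches: int
    gaps: int
    percent_identity: float


@dataclass
class IgBlastRecord:
    """One query's parsed IgBLAST block, before conversion."""

    query_id: str
    rearrangement_summary: dict[str, str] = field(default_factory=dict)
    alignment_summary: list[RegionRow] = field(default_factory=list)
    junction_details: list[str] = field(default_factory=list)
    hits: list[HitRow] = field(default_factory=list)


_SUMMARY_KEYS = {
    "top v gene match": "v_call",
    "top d gene match": "d_call",
    "top j gene match": "j_call",
    "chain type": "chain_type",
    "stop codon": "stop_codon",
    "v-j frame": "vj_frame",
    "productive": "productive",
    "strand": "strand",
}


def _parse_field_names(comment: str) -> list[str]:
    # skip decorations like the "(D)" in "V-(D)-J": the field list is the
    # last parenthesized group containing commas
    groups = [g for g in re.findall(r"\(([^()]*)\)", comment) if "," in g]
    if not groups:
        return []
    return [f.strip().lower() for f in groups[-1].split(",")]


def parse_igblast_stream(source: Union[str, Path, TextIO, Iterable[str]]) -> list[IgBlastRecord]:
    """Parse IgBLAST tabular-with-comments output into records, in file order."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return list(_parse_lines(fh))
    return list(_parse_lines(source))


_SECTION_NONE = 0
_SECTION_SUMMARY = 1
_SECTION_JUNCTION = 2
_SECTION_ALIGNMENT = 3
_SECTION_HITS = 4


def _parse_lines(lines: Iterable[str]) -> Iterator[IgBlastRecord]:
    record: Optional[IgBlastRecord] = None
    section = _SECTION_NONE
    summary_fields: list[str] = []
    hit_fields: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            comment = line[1:].strip()
            lower = comment.lower()
            if lower.startswith("query:"):
                if record is not None:
                    yield record
                record = IgBlastRecord(query_id=comment[len("Query:") :].strip())
                section = _SECTION_NONE
            elif "rearrangement summary" in lower:
                section = _SECTION_SUMMARY
                summary_fields = _parse_field_names(comment)
            elif "junction details" in lower:
                section = _SECTION_JUNCTION
            elif lower.startswith("alignment summary"):
                section = _SECTION_ALIGNMENT
            elif lower.startswith("hit table"):
                section = _SECTION_HITS
                hit_fields = []
            elif lower.startswith("fields:"):
                hit_fields = [f.strip().lower() for f in comment[len("Fields:") :].split(",")]
            elif lower.startswith(("igblastn", "igblastp", "blastn", "database:",
                                   "domain classification", "blast processed",
                                   "total queries", "total identifiable",
                                   "0 hits found")) or re.match(r"\d+ hits found", lower):
                continue
            else:
                raise IgBlastParseError(f"unrecognized header {line!r}", lineno)
            continue
        if record is None:
            raise IgBlastParseError("data line before any '# Query:' header", lineno)
        fields = line.split("\t")
        if section == _SECTION_SUMMARY:
            _parse_summary_row(record, summary_fields, fields)
        elif section == _SECTION_JUNCTION:
            record.junction_details = [f for f in fields if f]
        elif section == _SECTION_ALIGNMENT:
            row = _parse_region_row(fields, lineno)
            if row is not None:
                record.alignment_summary.append(row)
        elif section == _SECTION_HITS:
            record.hits.append(_parse_hit_row(fields, hit_fields, lineno))
        else:
            raise IgBlastParseError(f"unexpected data line {line!r}", lineno)
    if record is not None:
        yield record


def _parse_summary_row(record: IgBlastRecord, names: list[str], fields: list[str]) -> None:
    if not names:
        names = list(_SUMMARY_KEYS)[: len(fields)]
    for name, value in zip(names, fields):
        key = _SUMMARY_KEYS.get(name, name.replace(" ", "_"))
        record.rearrangement_summary[key] = value


def _parse_region_row(fields: list[str], lineno: int) -> Optional[RegionRow]:
    name = fields[0].strip()
    if len(fields) < 8:
        raise IgBlastParseError(
            f"alignment-summary row has {len(fields)} columns, expected 8", lineno
        )
    # Totals and rows without coordinates (N/A) carry no region interval.
    if name.lower().startswith("total") or fields[1] in ("N/A", ""):
        return None
    try:
        return RegionRow(
            name=name,
            start=int(fields[1]),
            end=int(fields[2]),
            length=int(fields[3]),
            matches=int(fields[4]),
            mismatches=int(fields[5]),
            gaps=int(fields[6]),
            percent_identity=float(fields[7]),
        )
    except ValueError as e:
        raise IgBlastParseError(f"bad alignment-summary row: {e}", lineno) from e


_HIT_COLUMNS = {
    "query id": None,
    "subject id": ("subject_name", str),
    "% identity": ("percent_identity", float),
    "alignment length": ("alignment_length", int),
    "mismatches": ("mismatches", int),
    "gap opens": ("gap_opens", int),
    "q. start": ("q_start", int),
    "q. end": ("q_end", int),
    "s. start": ("s_start", int),
    "s. end": ("s_end", int),
    "evalue": ("e_value", float),
    "bit score": ("bit_score", float),
    "btop": ("btop", str),
}


def _parse_hit_row(fields: list[str], names: list[str], lineno: int) -> HitRow:
    if not names:
        names = [n for n in _HIT_COLUMNS]
    # first column is the chain type of the hit (V/D/J), before the named fields
    expected = 1 + len(names)
    if len(fields) != expected:
        raise IgBlastParseError(
            f"hit row has {len(fields)} columns, expected {expected}", lineno
        )
    kwargs: dict = {"segment_type": fields[0].strip()}
    for name, value in zip(names, fields[1:]):
        spec = _HIT_COLUMNS.get(name)
        if spec is None:
            continue
        attr, conv = spec
        try:
            kwargs[attr] = conv(value)
        except ValueError as e:
            raise IgBlastParseError(f"bad value {value!r} for {name!r}", lineno) from e
    missing = {"btop", "q_start", "q_end", "s_start", "s_end", "bit_score"} - set(kwargs)
    if missing:
        raise IgBlastParseError(f"hit table lacks required columns: {sorted(missing)}", lineno)
    return HitRow(**kwargs)


# ---------------------------------------------------------------------------
# conversion


class InconsistentGroupError(ValueError):
    """Hits grouped as identical alignments disagree on alignment length."""


def group_hits(hits: list[HitRow], aligner_id: str = "1", gl_db_id: str = "1") -> list[SegmentMatch]:
    """Collapse identical alignments into segment matches.

    Hits sharing (segment type, read interval, BTOP, bit score) are one
    segment match with one germline entry per gene; matches are ordered
    all V (descending score), then D, then J, and numbered 1..n.
    """
    groups: dict[tuple, list[HitRow]] = {}
    order: list[tuple] = []
    for hit in hits:
        key = (hit.segment_type, hit.q_start, hit.q_end, hit.btop, hit.bit_score)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(hit)

    by_type: dict[str, list[tuple]] = {"V": [], "D": [], "J": []}
    for key in order:
        by_type.setdefault(key[0], []).append(key)

    matches: list[SegmentMatch] = []
    next_id = 1
    next_gl_id = 1
    for seg_type in ("V", "D", "J"):
        keys = sorted(
            by_type.get(seg_type, []),
            key=lambda k: -k[4],  # descending bit score; stable on ties
        )
        for key in keys:
            rows = groups[key]
            lengths = {r.alignment_length for r in rows}
            if len(lengths) > 1:
                raise InconsistentGroupError(
                    f"identical alignments for {[r.subject_name for r in rows]} "
                    f"disagree on alignment_length: {sorted(lengths)}"
                )
            head = rows[0]
            ops = _btop.parse_btop(head.btop)
            stats = _btop.summarize(ops)
            flags = _btop.stats_to_flags(stats)
            gl_matches = []
            for row in rows:
                gl_matches.append(
                    GlSegMatch(
                        gl_seg_match_id=str(next_gl_id),
                        segment_type=seg_type,
                        name=row.subject_name,
                        gl_pos0=row.s_start - 1,
                        gl_db_id=gl_db_id,
                        aligner_id=aligner_id,
                    )
                )
                next_gl_id += 1
            matches.append(
                SegmentMatch(
                    segment_match_id=str(next_id),
                    read_pos0=head.q_start - 1,
                    read_len=head.q_end - head.q_start + 1,
                    gl_len=ops.gl_span,
                    identity=round(stats.identity, 1),
                    score=head.bit_score,
                    btop=head.btop,
                    gl_seg_matches=gl_matches,
                    annotations=AnnotationFlags(
                        insertions=flags.insertions,
                        deletions=flags.deletions,
                        substitutions=flags.substitutions,
                        out_frame_indel=flags.out_frame_indel,
                    ),
                )
            )
            next_id += 1
    return matches


def select_combination(matches: list[SegmentMatch]) -> Combination:
    """Pick the top-scoring segment match of each type, in V, D, J order.

    ``matches`` must be in :func:`group_hits` order (per type, descending
    score), so the first match of each type wins — including ties, where
    the first-listed germline alignment is kept.
    """
    if not matches:
        raise ValueError("cannot select a combination from zero segment matches")
    chosen: dict[str, str] = {}
    for m in matches:
        seg_type = m.gl_seg_matches[0].segment_type
        if seg_type not in chosen:
            chosen[seg_type] = m.segment_match_id
    segments = [chosen[t] for t in ("V", "D", "J") if t in chosen]
    return Combination(segments=segments)


def map_regions(
    record: IgBlastRecord,
    combo: Combination,
    matches: list[SegmentMatch],
    aligner_id: str = "1",
) -> list[Region]:
    """Build region annotations: summary rows plus computed junctions.

    Summary rows convert 1-based inclusive [from, to] to 0-based
    ``read_pos0``/``read_len``.  Junction regions span the read interval
    between adjacent segment matches of the combination (VD and DJ for
    heavy-type chains, VJ when no D match exists); zero-length junctions
    mark abutting segments, and overlapping segments yield no junction.
    """
    regions = [
        Region(
            name=row.name,
            aligner_id=aligner_id,
            read_pos0=row.start - 1,
            read_len=row.end - row.start + 1,
        )
        for row in record.alignment_summary
    ]
    by_id = {m.segment_match_id: m for m in matches}
    by_type: dict[str, SegmentMatch] = {}
    for sid in combo.segments:
        m = by_id[sid]
        by_type[m.gl_seg_matches[0].segment_type] = m

    def junction(name: str, left: SegmentMatch, right: SegmentMatch) -> Optional[Region]:
        start = left.read_pos0 + left.read_len
        length = right.read_pos0 - start
        if length < 0:
            return None
        return Region(name=name, aligner_id=aligner_id, read_pos0=start, read_len=length)

    if "V" in by_type and "D" in by_type:
        r = junction("VD_junction", by_type["V"], by_type["D"])
        if r is not None:
            regions.append(r)
    if "D" in by_type and "J" in by_type:
        r = junction("DJ_junction", by_type["D"], by_type["J"])
        if r is not None:
            regions.append(r)
    if "V" in by_type and "J" in by_type and "D" not in by_type:
        r = junction("VJ_junction", by_type["V"], by_type["J"])
        if r is not None:
            regions.append(r)
    return regions


def summary_to_flags(record: IgBlastRecord) -> AnnotationFlags:
    """Map rearrangement-summary fields onto annotation flags.

    Absent fields leave the corresponding flag unset.
    """
    s = record.rearrangement_summary
    stop = s.get("stop_codon")
    frame = s.get("vj_frame")
    strand = s.get("strand")
    return AnnotationFlags(
        stop_codon=(stop == "Yes") if stop is not None else None,
        out_frame_vdj=(frame == "Out-of-frame") if frame is not None else None,
        inverted=(strand == "-") if strand is not None else None,
    )


def convert(
    source: Union[str, Path, TextIO, Iterable[str]],
    aligner: Aligner,
    db: GermlineDb,
    generator: Generator,
) -> Document:
    """Convert a whole IgBLAST tabular file into a VDJML document."""
    meta = Meta(generator=generator, aligners=[aligner], germline_dbs=[db])
    doc = Document(meta=meta)
    for record in parse_igblast_stream(source):
        try:
            doc.reads.append(convert_record(record, aligner.aligner_id, db.gl_db_id))
        except (ValueError, _btop.BtopError) as e:
            raise ValueError(f"query {record.query_id!r}: {e}") from e
    return doc


def convert_record(record: IgBlastRecord, aligner_id: str, gl_db_id: str) -> Read:
    """Convert one parsed IgBLAST block into a VDJML read entry."""
    read = Read(read_id=record.query_id)
    if not record.hits:
        return read
    matches = group_hits(record.hits, aligner_id=aligner_id, gl_db_id=gl_db_id)
    combo = select_combination(matches)
    combo.regions = map_regions(record, combo, matches, aligner_id=aligner_id)
    summary_flags = summary_to_flags(record)
    if not summary_flags.is_empty() and combo.segments:
        # read-level flags ride on the combination's first (V) segment match
        first = next(m for m in matches if m.segment_match_id == combo.segments[0])
        first.annotations = AnnotationFlags(
            insertions=first.annotations.insertions,
            deletions=first.annotations.deletions,
            substitutions=first.annotations.substitutions,
            out_frame_indel=first.annotations.out_frame_indel,
            stop_codon=summary_flags.stop_codon,
            out_frame_vdj=summary_flags.out_frame_vdj,
            inverted=summary_flags.inverted,
        )
    read.alignments.append(Alignment(segment_matches=matches, combinations=[combo]))
    return read
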