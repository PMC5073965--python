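"""Deterministic IgBLAST-dialect fixtures with paired ground-truth documents.

Two generators, both returning ``(igblast_text, expected_document)``:

* :func:`make_canonical_fixture` — a single IGH read whose hit table
  reproduces the classic worked example of the format: a V region that
  aligns identically to IGHV3-23*01 and IGHV3-23D*01 (one segment match,
  two germline entries), two distinct placements of IGHD2-21*01 with
  IGHD2-21*02 identical to the first, a best J hit to IGHJ4*02, and
  lower-scoring alternatives — seven segment matches in all, with the
  top combination [1, 3, 5].

* :func:`make_random_fixture` — seeded random reads with V/(D)/J hits
  whose BTOP strings are simulated column by column, so every printed
  statistic is derived from the same ground truth the expected document
  records.

The mismatch positions of the canonical V alignment follow a modular
rule — a substitution at every alignment offset ``o`` with
``(o + 1) % 14 == 0`` and ``o <= 279`` over the gap-free 295-column
alignment — so its substitution count (20) and identity (93.2 %) are
computed, never transcribed.  Scores are synthetic and only order the
hits; germline sequences are never materialized because the format
stores coordinates and BTOPs, not bases.

This emulates IgBLAST's comment-delimited tabular dialect with known
ground truth; it is not a biologically realistic repertoire simulator
(no somatic-hypermutation model, no junction chemistry).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from . import btop as _btop
from .btop import BtopOps, MatchRun, Mismatch, ReadDeletion, ReadInsertion
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
    "FixtureParams",
    "default_meta",
    "make_canonical_fixture",
    "make_random_fixture",
    "canonical_mismatch_offsets",
    "PRESETS",
]

ALIGNER_ID = "1"
GL_DB_ID = "1"

_BASES = "ACGT"


def default_meta() -> Meta:
    """The metadata block shared by all fixtures (fixed timestamp: deterministic)."""
    return Meta(
        generator=Generator(name="vdjml", version="1.0.0", time_gmt="2016-09-01T12:00:00Z"),
        aligners=[
            Aligner(
                aligner_id=ALIGNER_ID,
                name="IgBLAST",
                version="1.4.0",
                parameters="igblastn -germline_db_V gl_V -germline_db_D gl_D "
                "-germline_db_J gl_J -domain_system imgt -outfmt '7 std btop'",
            )
        ],
        germline_dbs=[
            GermlineDb(gl_db_id=GL_DB_ID, name="synthetic_gl", version="1", species="Homo sapiens")
        ],
    )


# ---------------------------------------------------------------------------
# canonical fixture


_V_LEN = 295
_V_READ_POS0 = 123  # 1-based q_start 124, q_end 418


def canonical_mismatch_offsets() -> list[int]:
    """Alignment offsets carrying a substitution in the canonical V BTOP."""
    return [o for o in range(_V_LEN) if (o + 1) % 14 == 0 and o <= 279]


def _btop_from_mismatch_offsets(length: int, offsets: list[int],
                                read_base: str = "A", gl_base: str = "G") -> str:
    mism = set(offsets)
    ops: list = []
    run = 0
    for o in range(length):
        if o in mism:
            if run:
                ops.append(MatchRun(run))
                run = 0
            ops.append(Mismatch(read_base, gl_base))
        else:
            run += 1
    if run:
        ops.append(MatchRun(run))
    return _btop.serialize_btop(BtopOps(tuple(ops)))


@dataclass(frozen=True)
class _Hit:
    segment_type: str
    name: str
    q_start: int  # 1-based
    s_start: int  # 1-based
    btop: str
    bit_score: float
    e_value: float


def _hit_row_text(query_id: str, hit: _Hit) -> str:
    ops = _btop.parse_btop(hit.btop)
    stats = _btop.summarize(ops)
    gap_opens = _count_gap_opens(ops)
    cols = [
        hit.segment_type,
        query_id,
        hit.name,
        f"{stats.identity:.3f}",
        str(stats.matches + stats.substitutions + stats.insertions + stats.deletions),
        str(stats.substitutions),
        str(gap_opens),
        str(hit.q_start),
        str(hit.q_start + ops.read_span - 1),
        str(hit.s_start),
        str(hit.s_start + ops.gl_span - 1),
        f"{hit.e_value:g}",
        f"{hit.bit_score:g}",
        hit.btop,
    ]
    return "\t".join(cols)


def _count_gap_opens(ops: BtopOps) -> int:
    opens = 0
    prev_gap = None
    for op in ops.ops:
        if isinstance(op, ReadInsertion):
            kind = "ins"
        elif isinstance(op, ReadDeletion):
            kind = "del"
        else:
            kind = None
        if kind and kind != prev_gap:
            opens += 1
        prev_gap = kind
    return opens


_FIELDS_COMMENT = (
    "# Fields: query id, subject id, % identity, alignment length, mismatches, "
    "gap opens, q. start, q. end, s. start, s. end, evalue, bit score, BTOP"
)


def _block_text(
    query_id: str,
    summary: Optional[list[str]],
    junction: Optional[list[str]],
    summary_rows: list[tuple[str, int, int]],
    v_mismatch_read_pos1: set[int],
    hits: list[_Hit],
) -> str:
    """Render one query block in IgBLAST comment-delimited tabular form."""
    lines = [f"# Query: {query_id}"]
    if summary is not None:
        lines.append(
            "# V-(D)-J rearrangement summary for query sequence (Top V gene match, "
            "Top D gene match, Top J gene match, Chain type, stop codon, V-J frame, "
            "Productive, Strand)"
        )
        lines.append("\t".join(summary))
    if junction is not None:
        lines.append(
            "# V-(D)-J junction details based on top germline gene matches "
            "(V end, V-D junction, D region, D-J junction, J start)"
        )
        lines.append("\t".join(junction))
    if summary_rows:
        lines.append(
            "# Alignment summary between query and top germline V gene hit "
            "(from, to, length, matches, mismatches, gaps, percent identity)"
        )
        total_len = total_m = total_mm = 0
        for name, start, end in summary_rows:
            length = end - start + 1
            mismatches = sum(1 for p in v_mismatch_read_pos1 if start <= p <= end)
            matches = length - mismatches
            pct = 100.0 * matches / length
            lines.append(
                f"{name}\t{start}\t{end}\t{length}\t{matches}\t{mismatches}\t0\t{pct:.1f}"
            )
            total_len += length
            total_m += matches
            total_mm += mismatches
        pct = 100.0 * total_m / total_len if total_len else 0.0
        lines.append(f"Total\tN/A\tN/A\t{total_len}\t{total_m}\t{total_mm}\t0\t{pct:.1f}")
    lines.append("# Hit table (the first field indicates the chain type of the hit)")
    if hits:
        lines.append(_FIELDS_COMMENT)
        lines.append(f"# {len(hits)} hits found")
        lines.extend(_hit_row_text(query_id, h) for h in hits)
    else:
        lines.append("# 0 hits found")
    return "\n".join(lines) + "\n"


def _expected_match(
    match_id: int,
    gl_ids: list[int],
    hits: list[_Hit],
    flags_extra: Optional[AnnotationFlags] = None,
) -> SegmentMatch:
    """Build the ground-truth segment match for a group of identical hits."""
    head = hits[0]
    ops = _btop.parse_btop(head.btop)
    stats = _btop.summarize(ops)
    base = _btop.stats_to_flags(stats)
    annotations = AnnotationFlags(
        insertions=base.insertions,
        deletions=base.deletions,
        substitutions=base.substitutions,
        out_frame_indel=base.out_frame_indel,
        stop_codon=flags_extra.stop_codon if flags_extra else None,
        out_frame_vdj=flags_extra.out_frame_vdj if flags_extra else None,
        inverted=flags_extra.inverted if flags_extra else None,
    )
    return SegmentMatch(
        segment_match_id=str(match_id),
        read_pos0=head.q_start - 1,
        read_len=ops.read_span,
        gl_len=ops.gl_span,
        identity=round(stats.identity, 1),
        score=head.bit_score,
        btop=head.btop,
        gl_seg_matches=[
            GlSegMatch(
                gl_seg_match_id=str(gid),
                segment_type=h.segment_type,
                name=h.name,
                gl_pos0=h.s_start - 1,
                gl_db_id=GL_DB_ID,
                aligner_id=ALIGNER_ID,
            )
            for gid, h in zip(gl_ids, hits)
        ],
        annotations=annotations,
    )


def make_canonical_fixture() -> tuple[str, Document]:
    """The worked-example fixture: one IGH read, nine hit rows, seven matches."""
    query_id = "canonical_read_1"
    offsets = canonical_mismatch_offsets()
    v_btop = _btop_from_mismatch_offsets(_V_LEN, offsets)
    v_btop_alt = _btop_from_mismatch_offsets(_V_LEN, offsets + [286])

    # hit groups, best score first within each type
    v1 = _Hit("V", "IGHV3-23*01", 124, 1, v_btop, 406.0, 1e-115)
    v2 = _Hit("V", "IGHV3-23D*01", 124, 1, v_btop, 406.0, 1e-115)
    v3 = _Hit("V", "IGHV3-23D*02", 124, 1, v_btop_alt, 398.0, 2e-113)
    d1 = _Hit("D", "IGHD2-21*01", 423, 3, "14", 28.4, 0.002)
    d2 = _Hit("D", "IGHD2-21*02", 423, 5, "14", 28.4, 0.002)
    d3 = _Hit("D", "IGHD2-21*01", 425, 1, "12", 22.0, 0.11)
    j1 = _Hit("J", "IGHJ4*02", 441, 7, "47", 93.8, 2e-22)
    j2 = _Hit("J", "IGHJ4*01", 441, 7, "20AG26", 87.9, 1e-20)
    j3 = _Hit("J", "IGHJ5*02", 443, 11, "15CT29", 80.2, 3e-18)
    hits = [v1, v2, v3, d1, d2, d3, j1, j2, j3]

    summary = ["IGHV3-23*01,IGHV3-23D*01", "IGHD2-21*01", "IGHJ4*02",
               "VH", "No", "In-frame", "Yes", "+"]
    junction = ["TGTGCG", "GGAT", "AGTGGCTGGTA", "CTAC", "TTTGAC"]
    summary_rows = [
        ("FR1", 124, 198),
        ("CDR1", 199, 222),
        ("FR2", 223, 273),
        ("CDR2", 274, 297),
        ("FR3", 298, 411),
    ]
    v_mismatch_read_pos1 = {124 + o for o in offsets}
    text = _block_text(query_id, summary, junction, summary_rows, v_mismatch_read_pos1, hits)

    summary_flags = AnnotationFlags(stop_codon=False, out_frame_vdj=False, inverted=False)
    matches = [
        _expected_match(1, [1, 2], [v1, v2], flags_extra=summary_flags),
        _expected_match(2, [3], [v3]),
        _expected_match(3, [4, 5], [d1, d2]),
        _expected_match(4, [6], [d3]),
        _expected_match(5, [7], [j1]),
        _expected_match(6, [8], [j2]),
        _expected_match(7, [9], [j3]),
    ]
    regions = [
        Region(name=n, aligner_id=ALIGNER_ID, read_pos0=s - 1, read_len=e - s + 1)
        for n, s, e in summary_rows
    ]
    # V ends at 123 + 295 = 418 on the read; D [422, 436); J [440, 487)
    regions.append(Region(name="VD_junction", aligner_id=ALIGNER_ID, read_pos0=418, read_len=4))
    regions.append(Region(name="DJ_junction", aligner_id=ALIGNER_ID, read_pos0=436, read_len=4))
    combo = Combination(segments=["1", "3", "5"], regions=regions)
    read = Read(read_id=query_id,
                alignments=[Alignment(segment_matches=matches, combinations=[combo])])
    return text, Document(meta=default_meta(), reads=[read])


# ---------------------------------------------------------------------------
# random fixtures


@dataclass(frozen=True)
class FixtureParams:
    """Knobs for the random fixture generator.

    Rates are per alignment column; interval bounds are in nucleotides on
    the read.  Defaults emulate lightly mutated IGH reads: a long V match,
    a short D, a J in the tens of bases, with a few percent substitutions
    and rare short indels.
    """

    substitution_rate: float = 0.05
    insertion_rate: float = 0.01
    deletion_rate: float = 0.01
    v_len_range: tuple[int, int] = (150, 300)
    d_len_range: tuple[int, int] = (8, 20)
    j_len_range: tuple[int, int] = (30, 50)
    junction_range: tuple[int, int] = (0, 8)
    p_no_hits: float = 0.1
    p_no_d: float = 0.2
    p_shared_v: float = 0.3
    p_extra_v: float = 0.4
    p_minus_strand: float = 0.15
    p_summary_rows: float = 0.7

    def validate(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate",
                     "p_no_hits", "p_no_d", "p_shared_v", "p_extra_v",
                     "p_minus_strand", "p_summary_rows"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.substitution_rate + self.insertion_rate + self.deletion_rate >= 1.0:
            raise ValueError("per-column mutation rates must sum to < 1")
        for name in ("v_len_range", "d_len_range", "j_len_range", "junction_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a non-negative (lo, hi) with lo <= hi")


def _random_btop(rng: random.Random, read_len: int, params: FixtureParams) -> str:
    """Simulate an alignment column by column until read_len is consumed."""
    ops: list = []
    consumed = 0

    def push_match() -> None:
        if ops and isinstance(ops[-1], MatchRun):
            ops[-1] = MatchRun(ops[-1].length + 1)
        else:
            ops.append(MatchRun(1))

    while consumed < read_len:
        r = rng.random()
        if r < params.substitution_rate:
            gl = rng.choice(_BASES)
            rd = rng.choice([b for b in _BASES if b != gl])
            ops.append(Mismatch(rd, gl))
            consumed += 1
        elif r < params.substitution_rate + params.insertion_rate:
            ops.append(ReadInsertion(rng.choice(_BASES)))
            consumed += 1
        elif r < params.substitution_rate + params.insertion_rate + params.deletion_rate:
            if consumed:  # avoid a leading read gap, which IgBLAST never emits
                ops.append(ReadDeletion(rng.choice(_BASES)))
        else:
            push_match()
            consumed += 1
    return _btop.serialize_btop(BtopOps(tuple(ops)))


def make_random_fixture(
    seed: int, n_reads: int, params: Optional[FixtureParams] = None
) -> tuple[str, Document]:
    """Generate ``n_reads`` random query blocks plus their ground-truth document."""
    if n_reads < 0:
        raise ValueError(f"n_reads must be >= 0, got {n_reads}")
    params = params or FixtureParams()
    params.validate()
    rng = random.Random(seed)
    blocks: list[str] = []
    reads: list[Read] = []

    for i in range(n_reads):
        query_id = f"read_{seed}_{i:04d}"
        if rng.random() < params.p_no_hits:
            blocks.append(_block_text(query_id, None, None, [], set(), []))
            reads.append(Read(read_id=query_id))
            continue
        blocks_i, read = _one_random_read(rng, query_id, params)
        blocks.append(blocks_i)
        reads.append(read)

    return "".join(blocks), Document(meta=default_meta(), reads=reads)


def _one_random_read(
    rng: random.Random, query_id: str, params: FixtureParams
) -> tuple[str, Read]:
    has_d = rng.random() >= params.p_no_d
    v_pos0 = rng.randint(0, 30)
    v_read_len = rng.randint(*params.v_len_range)
    v_btop = _random_btop(rng, v_read_len, params)
    v_names = ["IGHV%d-%d*01" % (rng.randint(1, 7), rng.randint(1, 80))]
    if rng.random() < params.p_shared_v:
        v_names.append(v_names[0].replace("*01", "*02"))

    next_start = v_pos0 + v_read_len + rng.randint(*params.junction_range)
    d_hits: list[_Hit] = []
    if has_d:
        d_len = rng.randint(*params.d_len_range)
        d_name = "IGHD%d-%d*01" % (rng.randint(1, 7), rng.randint(1, 30))
        d_hits.append(_Hit("D", d_name, next_start + 1, rng.randint(1, 6), str(d_len),
                           round(rng.uniform(20, 35), 1), 0.01))
        next_start = next_start + d_len + rng.randint(*params.junction_range)
    j_len = rng.randint(*params.j_len_range)
    j_btop = _random_btop(rng, j_len, params)
    j_name = "IGHJ%d*0%d" % (rng.randint(1, 6), rng.randint(1, 2))
    j_score = round(rng.uniform(60, 95), 1)

    v_score = round(rng.uniform(300, 450), 1)
    v_hits = [_Hit("V", name, v_pos0 + 1, 1, v_btop, v_score, 1e-100) for name in v_names]
    if rng.random() < params.p_extra_v:
        alt_len = max(50, v_read_len - rng.randint(5, 30))
        v_hits.append(
            _Hit("V", "IGHV%d-%d*03" % (rng.randint(1, 7), rng.randint(1, 80)),
                 v_pos0 + 1 + rng.randint(0, 4), rng.randint(1, 5),
                 _random_btop(rng, alt_len, params),
                 round(v_score - rng.uniform(5, 50), 1), 1e-90)
        )
    j_hits = [_Hit("J", j_name, next_start + 1, rng.randint(1, 12), j_btop, j_score, 1e-15)]

    hits = v_hits + d_hits + j_hits
    strand = "-" if rng.random() < params.p_minus_strand else "+"
    stop = rng.choice(["Yes", "No"])
    frame = rng.choice(["In-frame", "Out-of-frame"])
    summary = [",".join(v_names), d_hits[0].name if d_hits else "N/A", j_name,
               "VH", stop, frame, "Yes" if stop == "No" and frame == "In-frame" else "No",
               strand]

    summary_rows: list[tuple[str, int, int]] = []
    v_mismatch_pos1: set[int] = set()
    if rng.random() < params.p_summary_rows:
        v_mismatch_pos1 = _mismatch_read_positions1(v_btop, v_pos0)
        bounds = sorted(rng.sample(range(v_pos0 + 2, v_pos0 + v_read_len), 4))
        names = ["FR1", "CDR1", "FR2", "CDR2", "FR3"]
        edges = [v_pos0 + 1] + bounds + [v_pos0 + v_read_len]
        for k, name in enumerate(names):
            start, end = edges[k], edges[k + 1] - (0 if k == len(names) - 1 else 1)
            if start <= end:
                summary_rows.append((name, start, end))

    text = _block_text(query_id, summary, None, summary_rows, v_mismatch_pos1, hits)

    # ground truth: groups in emitted order are already per-type, best first
    matches: list[SegmentMatch] = []
    match_id = 1
    gl_id = 1
    groups: list[list[_Hit]] = []
    for seg_hits in (v_hits, d_hits, j_hits):
        shared = [h for h in seg_hits if h.btop == seg_hits[0].btop
                  and h.q_start == seg_hits[0].q_start and h.bit_score == seg_hits[0].bit_score]
        rest = [h for h in seg_hits if h not in shared]
        groups.append(shared)
        groups.extend([h] for h in rest)
    groups = [g for g in groups if g]
    summary_flags = AnnotationFlags(
        stop_codon=stop == "Yes",
        out_frame_vdj=frame == "Out-of-frame",
        inverted=strand == "-",
    )
    combo_ids: dict[str, str] = {}
    for group in groups:
        seg_type = group[0].segment_type
        extra = summary_flags if seg_type not in combo_ids and match_id == 1 else None
        gl_ids = list(range(gl_id, gl_id + len(group)))
        matches.append(_expected_match(match_id, gl_ids, group, flags_extra=extra))
        if seg_type not in combo_ids:
            combo_ids[seg_type] = str(match_id)
        match_id += 1
        gl_id += len(group)

    combo = Combination(segments=[combo_ids[t] for t in ("V", "D", "J") if t in combo_ids])
    regions = [
        Region(name=n, aligner_id=ALIGNER_ID, read_pos0=s - 1, read_len=e - s + 1)
        for n, s, e in summary_rows
    ]
    by_type = {t: next(m for m in matches if m.segment_match_id == mid)
               for t, mid in combo_ids.items()}
    pairs = [("V", "D", "VD_junction"), ("D", "J", "DJ_junction")]
    if "D" not in by_type:
        pairs = [("V", "J", "VJ_junction")]
    for left, right, name in pairs:
        if left in by_type and right in by_type:
            start = by_type[left].read_pos0 + by_type[left].read_len
            length = by_type[right].read_pos0 - start
            if length >= 0:
                regions.append(Region(name=name, aligner_id=ALIGNER_ID,
                                      read_pos0=start, read_len=length))
    combo.regions = regions
    read = Read(read_id=query_id,
                alignments=[Alignment(segment_matches=matches, combinations=[combo])])
    return text, read


def _mismatch_read_positions1(btop_text: str, read_pos0: int) -> set[int]:
    """1-based read positions of mismatch columns in a BTOP."""
    ops = _btop.parse_btop(btop_text)
    pos = read_pos0  # 0-based
    out: set[int] = set()
    for op in ops.ops:
        if isinstance(op, MatchRun):
            pos += op.length
        elif isinstance(op, Mismatch):
            out.add(pos + 1)
            pos += 1
        elif isinstance(op, ReadInsertion):
            pos += 1
    return out


PRESETS = {
    "fig3": lambda seed=0, n_reads=1, params=None: make_canonical_fixture(),
    "random": make_random_fixture,
}
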