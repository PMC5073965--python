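"""In-memory model of a VDJML 1.0 document.

A VDJML document records the results of aligning immune-receptor reads to
germline V, D and J gene segments.  It has two parts: a metadata block
(which software generated the file, which aligners produced the results,
which germline databases they were run against) and an ordered stream of
per-read results.  Reads are referenced by identifier only — the
nucleotide sequences stay in the FASTA/FASTQ source.

The model mirrors the element structure of the format:

* a ``Read`` holds one or more ``Alignment`` blocks;
* an ``Alignment`` holds ``SegmentMatch`` records — an aligned read
  interval tied to one or more germline segments whose alignments to that
  interval are identical — and ``Combination`` records naming the segment
  matches inferred to constitute the rearranged gene;
* identifier references (aligner_id, gl_db_id, segment_match_id) are
  opaque tokens whose integrity ``validate_document`` checks.

Coordinates: every ``*_pos0`` attribute is 0-based, and intervals are
``[pos0, pos0 + len)`` half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "AnnotationFlags",
    "AaSubstitution",
    "GlSegMatch",
    "SegmentMatch",
    "Region",
    "Combination",
    "Alignment",
    "Read",
    "Generator",
    "Aligner",
    "GermlineDb",
    "Meta",
    "Document",
    "Violation",
    "validate_document",
    "resolve_combination",
    "UnresolvedReferenceError",
    "VDJML_VERSION",
    "VDJ_NAMESPACE",
    "SEGMENT_TYPES",
]

VDJML_VERSION = "1.0"
VDJ_NAMESPACE = "http://vdjserver.org/vdjml/xsd/1/"
SEGMENT_TYPES = ("V", "D", "J")

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


@dataclass(frozen=True)
class AnnotationFlags:
    """Optional per-segment-match / per-region annotations.

    ``num_system`` names the codon numbering system (e.g. Kabat, IMGT);
    the mutation counts are relative to the germline; the booleans flag
    biologically notable events (premature stop codon, mutated invariant
    residue, reverse-complement read, frame-shifting indel, out-of-frame
    V(D)J junction).
    """

    num_system: Optional[str] = None
    identity: Optional[float] = None
    score: Optional[float] = None
    insertions: Optional[int] = None
    deletions: Optional[int] = None
    substitutions: Optional[int] = None
    stop_codon: Optional[bool] = None
    mutated_invariant: Optional[bool] = None
    inverted: Optional[bool] = None
    out_frame_indel: Optional[bool] = None
    out_frame_vdj: Optional[bool] = None

    def is_empty(self) -> bool:
        return all(getattr(self, f) is None for f in self.__dataclass_fields__)


@dataclass(frozen=True)
class AaSubstitution:
    """An amino-acid change in the read relative to the germline.

    ``read_codon_pos0`` is the 0-based start of the affected codon in the
    read; the amino acids are single-letter codes ('X' for unknown).
    """

    read_codon_pos0: int
    germline_aa: str
    read_aa: str


@dataclass(frozen=True)
class GlSegMatch:
    """One germline gene segment participating in a segment match."""

    gl_seg_match_id: str
    segment_type: str  # V, D, or J
    name: str  # database nomenclature, e.g. IGHV3-23*01
    gl_pos0: int  # 0-based first aligned germline position
    gl_db_id: str
    aligner_id: str


@dataclass
class SegmentMatch:
    """An aligned read interval shared by one or more germline segments.

    The interval is ``[read_pos0, read_pos0 + read_len)`` on the read and
    covers ``gl_len`` germline positions.  When the alignments of several
    germline segments to this interval are identical they share one
    SegmentMatch, each contributing a :class:`GlSegMatch`.
    """

    segment_match_id: str
    read_pos0: int
    read_len: int
    gl_len: int
    gl_seg_matches: list[GlSegMatch]
    identity: Optional[float] = None  # percent, [0, 100]
    score: Optional[float] = None
    btop: Optional[str] = None
    aa_substitutions: list[AaSubstitution] = field(default_factory=list)
    annotations: AnnotationFlags = field(default_factory=AnnotationFlags)


@dataclass
class Region:
    """A named annotated interval on the read (FR1, CDR2, VD_junction, ...)."""

    name: str
    aligner_id: str
    read_pos0: int
    read_len: int  # zero-length junctions are legal when segments abut
    annotations: AnnotationFlags = field(default_factory=AnnotationFlags)


@dataclass
class Combination:
    """The inferred V(D)J rearrangement.

    ``segments`` lists segment_match_id references, at most one per
    segment type, ordered V then D (if any) then J.
    """

    segments: list[str]
    regions: list[Region] = field(default_factory=list)


@dataclass
class Alignment:
    """All alignment output for one read from one or more aligners."""

    segment_matches: list[SegmentMatch] = field(default_factory=list)
    combinations: list[Combination] = field(default_factory=list)


@dataclass
class Read:
    """Results for one sequencing read, keyed by its FASTA/FASTQ identifier."""

    read_id: str
    alignments: list[Alignment] = field(default_factory=list)


@dataclass
class Generator:
    """The software that wrote the VDJML file (all fields required)."""

    name: str
    version: str
    time_gmt: str  # ISO-8601 timestamp, GMT, 'Z' suffix


@dataclass
class Aligner:
    """A sequence-to-germline alignment program used to produce results."""

    aligner_id: str
    name: str
    version: Optional[str] = None
    parameters: Optional[str] = None  # invocation / command line


@dataclass
class GermlineDb:
    """A germline gene-segment database (all fields required)."""

    gl_db_id: str
    name: str
    version: str
    species: str


@dataclass
class Meta:
    """Shared metadata: generator, aligners, germline databases.

    ``extensions`` holds foreign-namespace XML payload, preserved opaquely
    (as serialized element text) and re-emitted on write.
    """

    generator: Generator
    aligners: list[Aligner] = field(default_factory=list)
    germline_dbs: list[GermlineDb] = field(default_factory=list)
    extensions: list[str] = field(default_factory=list)


@dataclass
class Document:
    """One VDJML document: metadata plus an ordered stream of read results."""

    meta: Meta
    reads: list[Read] = field(default_factory=list)
    version: str = VDJML_VERSION
    extensions: list[str] = field(default_factory=list)  # foreign payload under read_results


@dataclass(frozen=True)
class Violation:
    """One failed validation rule, pinpointing the offending element."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: [{self.rule}] {self.message}"


class UnresolvedReferenceError(KeyError):
    """A combination references a segment_match_id absent from its alignment."""


def resolve_combination(alignment: Alignment, combo: Combination) -> list[SegmentMatch]:
    """Return the SegmentMatch records referenced by ``combo.segments``, in order.

    Raises
    ------
    UnresolvedReferenceError
        If any referenced identifier has no SegmentMatch in ``alignment``.
    """
    by_id = {m.segment_match_id: m for m in alignment.segment_matches}
    out = []
    for sid in combo.segments:
        if sid not in by_id:
            raise UnresolvedReferenceError(
                f"combination references unknown segment_match_id {sid!r}"
            )
        out.append(by_id[sid])
    return out


def validate_document(doc: Document) -> list[Violation]:
    """Check every model invariant; return one Violation per breach.

    An empty return value means the document is valid.  Violations are
    data, not exceptions: a reader can report all problems at once.
    """
    from .btop import BtopError, parse_btop  # deferred: btop imports AnnotationFlags

    v: list[Violation] = []

    def bad(path: str, rule: str, message: str) -> None:
        v.append(Violation(path, rule, message))

    if not doc.version:
        bad("/vdjml", "version-nonempty", "document version must be non-empty")

    meta = doc.meta
    if not (meta.generator.name and meta.generator.version and meta.generator.time_gmt):
        bad("/vdjml/meta/generator", "generator-required",
            "generator name, version and time_gmt are all required")

    aligner_ids: set[str] = set()
    for i, al in enumerate(meta.aligners):
        path = f"/vdjml/meta/aligner[{i}]"
        if not al.aligner_id:
            bad(path, "aligner-id-nonempty", "aligner_id must be non-empty")
        elif al.aligner_id in aligner_ids:
            bad(path, "aligner-id-unique", f"duplicate aligner_id {al.aligner_id!r}")
        aligner_ids.add(al.aligner_id)

    db_ids: set[str] = set()
    for i, db in enumerate(meta.germline_dbs):
        path = f"/vdjml/meta/germline_db[{i}]"
        if not (db.gl_db_id and db.name and db.version and db.species):
            bad(path, "germline-db-required",
                "gl_db_id, name, version and species are all required")
        if db.gl_db_id in db_ids:
            bad(path, "gl-db-id-unique", f"duplicate gl_db_id {db.gl_db_id!r}")
        db_ids.add(db.gl_db_id)

    read_ids: set[str] = set()
    for r, read in enumerate(doc.reads):
        rpath = f"/vdjml/read_results/read[{r}]"
        if not read.read_id:
            bad(rpath, "read-id-nonempty", "read_id must be non-empty")
        elif read.read_id in read_ids:
            bad(rpath, "read-id-unique", f"duplicate read_id {read.read_id!r}")
        read_ids.add(read.read_id)

        for a, aln in enumerate(read.alignments):
            apath = f"{rpath}/alignment[{a}]"
            _validate_alignment(aln, apath, aligner_ids, db_ids, bad, parse_btop, BtopError)
    return v


def _validate_alignment(aln, apath, aligner_ids, db_ids, bad, parse_btop, BtopError):
    match_ids: set[str] = set()
    type_by_id: dict[str, set[str]] = {}
    for m, sm in enumerate(aln.segment_matches):
        mpath = f"{apath}/segment_match[{m}]"
        if sm.segment_match_id in match_ids:
            bad(mpath, "segment-match-id-unique",
                f"duplicate segment_match_id {sm.segment_match_id!r}")
        match_ids.add(sm.segment_match_id)
        if sm.read_pos0 < 0:
            bad(mpath, "read-pos0-nonneg", f"read_pos0 {sm.read_pos0} < 0")
        if sm.read_len < 1:
            bad(mpath, "read-len-positive", f"read_len {sm.read_len} < 1")
        if sm.gl_len < 1:
            bad(mpath, "gl-len-positive", f"gl_len {sm.gl_len} < 1")
        if sm.identity is not None and not 0.0 <= sm.identity <= 100.0:
            bad(mpath, "identity-range", f"identity {sm.identity} outside [0, 100]")
        if sm.btop is not None:
            try:
                ops = parse_btop(sm.btop)
            except BtopError as e:
                bad(mpath + "/btop", "btop-wellformed", str(e))
            else:
                if ops.read_span != sm.read_len:
                    bad(mpath + "/btop", "btop-read-span",
                        f"BTOP read span {ops.read_span} != read_len {sm.read_len}")
                if ops.gl_span != sm.gl_len:
                    bad(mpath + "/btop", "btop-gl-span",
                        f"BTOP germline span {ops.gl_span} != gl_len {sm.gl_len}")
        if not sm.gl_seg_matches:
            bad(mpath, "gl-seg-match-nonempty",
                "segment_match must have at least one gl_seg_match")
        types = set()
        for g, gsm in enumerate(sm.gl_seg_matches):
            gpath = f"{mpath}/gl_seg_match[{g}]"
            if gsm.segment_type not in SEGMENT_TYPES:
                bad(gpath, "segment-type", f"segment type {gsm.segment_type!r} not in V/D/J")
            else:
                types.add(gsm.segment_type)
            if gsm.gl_pos0 < 0:
                bad(gpath, "gl-pos0-nonneg", f"gl_pos0 {gsm.gl_pos0} < 0")
            if gsm.aligner_id not in aligner_ids:
                bad(gpath, "aligner-ref", f"unknown aligner_id {gsm.aligner_id!r}")
            if gsm.gl_db_id not in db_ids:
                bad(gpath, "gl-db-ref", f"unknown gl_db_id {gsm.gl_db_id!r}")
        type_by_id[sm.segment_match_id] = types
        _validate_flags(sm.annotations, mpath, bad)
        for s, sub in enumerate(sm.aa_substitutions):
            spath = f"{mpath}/aa_substitution[{s}]"
            if sub.read_codon_pos0 < 0:
                bad(spath, "codon-pos0-nonneg", f"read_codon_pos0 {sub.read_codon_pos0} < 0")
            for aa in (sub.germline_aa, sub.read_aa):
                if aa not in _AA_CODES:
                    bad(spath, "aa-code", f"{aa!r} is not a single-letter amino-acid code")

    for c, combo in enumerate(aln.combinations):
        cpath = f"{apath}/combination[{c}]"
        seen_types: list[str] = []
        for sid in combo.segments:
            if sid not in match_ids:
                bad(cpath, "combination-ref",
                    f"segments references unknown segment_match_id {sid!r}")
                continue
            types = type_by_id.get(sid, set())
            if len(types) == 1:
                seen_types.append(next(iter(types)))
        if len(seen_types) != len(set(seen_types)):
            bad(cpath, "combination-one-per-type",
                f"more than one segment match per type in {combo.segments!r}")
        order = [t for t in seen_types if t in SEGMENT_TYPES]
        if order != sorted(order, key=SEGMENT_TYPES.index):
            bad(cpath, "combination-vdj-order",
                f"segments not ordered V, D, J: types {seen_types!r}")
        for rg, region in enumerate(combo.regions):
            gpath = f"{cpath}/region[{rg}]"
            if region.read_pos0 < 0:
                bad(gpath, "region-pos0-nonneg", f"read_pos0 {region.read_pos0} < 0")
            if region.read_len < 0:
                bad(gpath, "region-len-nonneg", f"read_len {region.read_len} < 0")
            if region.aligner_id not in aligner_ids:
                bad(gpath, "aligner-ref", f"unknown aligner_id {region.aligner_id!r}")
            _validate_flags(region.annotations, gpath, bad)


def _validate_flags(flags: AnnotationFlags, path: str, bad) -> None:
    if flags.identity is not None and not 0.0 <= flags.identity <= 100.0:
        bad(path, "identity-range", f"identity {flags.identity} outside [0, 100]")
    for name in ("insertions", "deletions", "substitutions"):
        val = getattr(flags, name)
        if val is not None and val < 0:
            bad(path, "count-nonneg", f"{name} {val} < 0")
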