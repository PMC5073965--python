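"""Streaming, schema-validating reader and writer for VDJML XML.

Both directions are incremental: the reader holds at most one ``vdj:read``
subtree in memory at a time (after the metadata block, which is parsed
eagerly on open), and the writer serializes each read as it is handed
over.  Gzip- and bzip2-compressed files are read and written transparently;
on read the codec is detected from magic bytes, on write from the sink's
extension.

The VDJML 1.0 XML Schema ships with the package (``vdjml-1.0.xsd``) and is
used by :func:`validate_file` alongside the model-level referential checks
from :func:`vdjml.model.validate_document`.
"""

from __future__ import annotations

import bz2
import copy as _copy
import gzip
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import BinaryIO, Iterator, Optional, Union

from lxml import etree

from .model import (
    AaSubstitution,
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
    VDJ_NAMESPACE,
    VDJML_VERSION,
    Violation,
    validate_document,
)

__all__ = [
    "detect_codec",
    "open_reader",
    "open_writer",
    "read_document",
    "write_document",
    "validate_file",
    "VdjmlReader",
    "VdjmlWriter",
    "ValidationReport",
    "NotVdjmlError",
    "VdjmlFormatWarning",
    "load_schema",
]

Source = Union[str, Path, BinaryIO]

_NS = {"vdj": VDJ_NAMESPACE}


def _q(tag: str) -> str:
    return f"{{{VDJ_NAMESPACE}}}{tag}"


class NotVdjmlError(ValueError):
    """The source is not a VDJML document (wrong root element or namespace)."""


class VdjmlFormatWarning(UserWarning):
    """Recoverable format surprises: unknown version, unknown vdj elements."""


# ---------------------------------------------------------------------------
# codec handling


def detect_codec(source: Source) -> str:
    """Return ``"gzip"``, ``"bzip2"`` or ``"plain"`` for a path or stream.

    Magic bytes win (``1f 8b`` gzip, ``BZh`` bzip2); if the source cannot
    be peeked the file extension decides; otherwise plain.
    """
    magic = b""
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            with open(path, "rb") as fh:
                magic = fh.read(3)
        except OSError as e:
            raise OSError(f"cannot read {path}: {e}") from e
        name = path.name
    else:
        name = getattr(source, "name", "") or ""
        if hasattr(source, "peek"):
            magic = source.peek(3)[:3]
        elif source.seekable():
            pos = source.tell()
            magic = source.read(3)
            source.seek(pos)
    if magic[:2] == b"\x1f\x8b":
        return "gzip"
    if magic[:3] == b"BZh":
        return "bzip2"
    if magic:
        return "plain"
    if str(name).endswith(".gz"):
        return "gzip"
    if str(name).endswith(".bz2"):
        return "bzip2"
    return "plain"


def _open_for_read(source: Source) -> BinaryIO:
    codec = detect_codec(source)
    if isinstance(source, (str, Path)):
        raw: BinaryIO = open(source, "rb")
    else:
        raw = source
    if codec == "gzip":
        return gzip.open(raw, "rb")
    if codec == "bzip2":
        return bz2.open(raw, "rb")
    return raw


def _open_for_write(sink: Source) -> BinaryIO:
    if isinstance(sink, (str, Path)):
        name = str(sink)
        if name.endswith(".gz"):
            return gzip.open(name, "wb")
        if name.endswith(".bz2"):
            return bz2.open(name, "wb")
        return open(name, "wb")
    return sink


# ---------------------------------------------------------------------------
# element <-> model conversion


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def _set_opt(el: etree._Element, name: str, value) -> None:
    if value is None:
        return
    if isinstance(value, bool):
        el.set(name, "true" if value else "false")
    elif isinstance(value, float):
        el.set(name, _fmt_float(value))
    else:
        el.set(name, str(value))


_FLAG_FIELDS = (
    "num_system",
    "insertions",
    "deletions",
    "substitutions",
    "stop_codon",
    "mutated_invariant",
    "inverted",
    "out_frame_indel",
    "out_frame_vdj",
)


def _set_flags(el: etree._Element, flags: AnnotationFlags, with_identity_score: bool) -> None:
    if with_identity_score:
        if flags.identity is not None:
            el.set("identity", f"{flags.identity:.1f}")
        _set_opt(el, "score", flags.score)
    for name in _FLAG_FIELDS:
        _set_opt(el, name, getattr(flags, name))


def _parse_bool(text: Optional[str]) -> Optional[bool]:
    if text is None:
        return None
    return text in ("true", "1")


def _parse_flags(el: etree._Element, with_identity_score: bool) -> AnnotationFlags:
    get = el.get
    return AnnotationFlags(
        num_system=get("num_system"),
        identity=float(get("identity")) if with_identity_score and get("identity") else None,
        score=float(get("score")) if with_identity_score and get("score") else None,
        insertions=int(get("insertions")) if get("insertions") else None,
        deletions=int(get("deletions")) if get("deletions") else None,
        substitutions=int(get("substitutions")) if get("substitutions") else None,
        stop_codon=_parse_bool(get("stop_codon")),
        mutated_invariant=_parse_bool(get("mutated_invariant")),
        inverted=_parse_bool(get("inverted")),
        out_frame_indel=_parse_bool(get("out_frame_indel")),
        out_frame_vdj=_parse_bool(get("out_frame_vdj")),
    )


def _payload_str(el: etree._Element) -> str:
    """Serialize a foreign element standalone: no tail, no inherited nsmaps."""
    clone = _copy.deepcopy(el)
    clone.tail = None
    etree.cleanup_namespaces(clone)
    return etree.tostring(clone).decode()


def meta_to_element(meta: Meta) -> etree._Element:
    el = etree.Element(_q("meta"), nsmap=_NS)
    gen = etree.SubElement(el, _q("generator"))
    gen.set("name", meta.generator.name)
    gen.set("version", meta.generator.version)
    gen.set("time_gmt", meta.generator.time_gmt)
    for al in meta.aligners:
        ael = etree.SubElement(el, _q("aligner"))
        ael.set("aligner_id", al.aligner_id)
        ael.set("name", al.name)
        _set_opt(ael, "version", al.version)
        if al.parameters is not None:
            etree.SubElement(ael, _q("parameters")).text = al.parameters
    for db in meta.germline_dbs:
        del_ = etree.SubElement(el, _q("germline_db"))
        del_.set("gl_db_id", db.gl_db_id)
        del_.set("name", db.name)
        del_.set("version", db.version)
        del_.set("species", db.species)
    for payload in meta.extensions:
        el.append(etree.fromstring(payload))
    return el


def element_to_meta(el: etree._Element) -> Meta:
    gen_el = el.find(_q("generator"))
    if gen_el is None:
        raise NotVdjmlError("vdj:meta lacks a vdj:generator element")
    generator = Generator(
        name=gen_el.get("name", ""),
        version=gen_el.get("version", ""),
        time_gmt=gen_el.get("time_gmt", ""),
    )
    aligners = []
    for ael in el.findall(_q("aligner")):
        pel = ael.find(_q("parameters"))
        aligners.append(
            Aligner(
                aligner_id=ael.get("aligner_id", ""),
                name=ael.get("name", ""),
                version=ael.get("version"),
                parameters=pel.text if pel is not None else None,
            )
        )
    dbs = [
        GermlineDb(
            gl_db_id=d.get("gl_db_id", ""),
            name=d.get("name", ""),
            version=d.get("version", ""),
            species=d.get("species", ""),
        )
        for d in el.findall(_q("germline_db"))
    ]
    extensions = [
        _payload_str(child)
        for child in el
        if isinstance(child.tag, str) and not child.tag.startswith(f"{{{VDJ_NAMESPACE}}}")
    ]
    return Meta(generator=generator, aligners=aligners, germline_dbs=dbs, extensions=extensions)


def read_to_element(read: Read) -> etree._Element:
    el = etree.Element(_q("read"), nsmap=_NS)
    el.set("read_id", read.read_id)
    for aln in read.alignments:
        ael = etree.SubElement(el, _q("alignment"))
        for sm in aln.segment_matches:
            mel = etree.SubElement(ael, _q("segment_match"))
            mel.set("segment_match_id", str(sm.segment_match_id))
            mel.set("read_pos0", str(sm.read_pos0))
            mel.set("read_len", str(sm.read_len))
            mel.set("gl_len", str(sm.gl_len))
            if sm.identity is not None:
                mel.set("identity", f"{sm.identity:.1f}")
            _set_opt(mel, "score", sm.score)
            _set_flags(mel, sm.annotations, with_identity_score=False)
            if sm.btop is not None:
                etree.SubElement(mel, _q("btop")).text = sm.btop
            for gsm in sm.gl_seg_matches:
                gel = etree.SubElement(mel, _q("gl_seg_match"))
                gel.set("gl_seg_match_id", str(gsm.gl_seg_match_id))
                gel.set("type", gsm.segment_type)
                gel.set("name", gsm.name)
                gel.set("gl_pos0", str(gsm.gl_pos0))
                gel.set("gl_db_id", str(gsm.gl_db_id))
                gel.set("aligner_id", str(gsm.aligner_id))
            for sub in sm.aa_substitutions:
                sel = etree.SubElement(mel, _q("aa_substitution"))
                sel.set("read_codon_pos0", str(sub.read_codon_pos0))
                sel.set("germline_aa", sub.germline_aa)
                sel.set("read_aa", sub.read_aa)
        for combo in aln.combinations:
            cel = etree.SubElement(ael, _q("combination"))
            cel.set("segments", " ".join(str(s) for s in combo.segments))
            for region in combo.regions:
                rel = etree.SubElement(cel, _q("region"))
                rel.set("name", region.name)
                rel.set("aligner_id", str(region.aligner_id))
                rel.set("read_pos0", str(region.read_pos0))
                rel.set("read_len", str(region.read_len))
                _set_flags(rel, region.annotations, with_identity_score=True)
    return el


def element_to_read(el: etree._Element) -> Read:
    read = Read(read_id=el.get("read_id", ""))
    for ael in el.findall(_q("alignment")):
        aln = Alignment()
        for mel in ael.findall(_q("segment_match")):
            btop_el = mel.find(_q("btop"))
            sm = SegmentMatch(
                segment_match_id=mel.get("segment_match_id", ""),
                read_pos0=int(mel.get("read_pos0", "0")),
                read_len=int(mel.get("read_len", "0")),
                gl_len=int(mel.get("gl_len", "0")),
                identity=float(mel.get("identity")) if mel.get("identity") else None,
                score=float(mel.get("score")) if mel.get("score") else None,
                btop=btop_el.text if btop_el is not None else None,
                gl_seg_matches=[
                    GlSegMatch(
                        gl_seg_match_id=g.get("gl_seg_match_id", ""),
                        segment_type=g.get("type", ""),
                        name=g.get("name", ""),
                        gl_pos0=int(g.get("gl_pos0", "0")),
                        gl_db_id=g.get("gl_db_id", ""),
                        aligner_id=g.get("aligner_id", ""),
                    )
                    for g in mel.findall(_q("gl_seg_match"))
                ],
                aa_substitutions=[
                    AaSubstitution(
                        read_codon_pos0=int(s.get("read_codon_pos0", "0")),
                        germline_aa=s.get("germline_aa", "X"),
                        read_aa=s.get("read_aa", "X"),
                    )
                    for s in mel.findall(_q("aa_substitution"))
                ],
                annotations=_parse_flags(mel, with_identity_score=False),
            )
            aln.segment_matches.append(sm)
        for cel in ael.findall(_q("combination")):
            combo = Combination(segments=cel.get("segments", "").split())
            for rel in cel.findall(_q("region")):
                combo.regions.append(
                    Region(
                        name=rel.get("name", ""),
                        aligner_id=rel.get("aligner_id", ""),
                        read_pos0=int(rel.get("read_pos0", "0")),
                        read_len=int(rel.get("read_len", "0")),
                        annotations=_parse_flags(rel, with_identity_score=True),
                    )
                )
            aln.combinations.append(combo)
        read.alignments.append(aln)
    return read


# ---------------------------------------------------------------------------
# reader


class VdjmlReader:
    """Incremental VDJML reader.

    The metadata block is available as :attr:`meta` immediately after
    construction; iterating over the handle yields :class:`~vdjml.model.Read`
    records one at a time, discarding each parsed subtree before the next
    is built.  Foreign-namespace elements directly under ``vdj:read_results``
    are collected into :attr:`extensions` as they are encountered.
    """

    def __init__(self, source: Source):
        self._stream = _open_for_read(source)
        self._events = etree.iterparse(self._stream, events=("start", "end"))
        self.meta: Optional[Meta] = None
        self.version: Optional[str] = None
        self.extensions: list[str] = []
        self._root: Optional[etree._Element] = None
        self._read_meta()

    def _read_meta(self) -> None:
        for event, el in self._events:
            if event == "start" and self._root is None:
                if el.tag != _q("vdjml"):
                    raise NotVdjmlError(
                        f"root element is {el.tag!r}, expected vdj:vdjml "
                        f"in namespace {VDJ_NAMESPACE}"
                    )
                self._root = el
                self.version = el.get("version", "")
                if self.version != VDJML_VERSION:
                    warnings.warn(
                        f"document version {self.version!r} differs from "
                        f"supported version {VDJML_VERSION!r}",
                        VdjmlFormatWarning,
                        stacklevel=4,
                    )
            elif event == "end" and el.tag == _q("meta"):
                self.meta = element_to_meta(el)
                return
        if self.meta is None:
            raise NotVdjmlError("no vdj:meta element found")

    def __iter__(self) -> Iterator[Read]:
        known = {_q("read"), _q("read_results")}
        for event, el in self._events:
            if event != "end":
                continue
            parent = el.getparent()
            in_results = parent is not None and parent.tag == _q("read_results")
            if el.tag == _q("read") and in_results:
                read = element_to_read(el)
                el.clear()
                if parent is not None:
                    while el.getprevious() is not None:
                        del parent[0]
                yield read
            elif in_results and isinstance(el.tag, str):
                if el.tag.startswith(f"{{{VDJ_NAMESPACE}}}"):
                    if el.tag not in known:
                        warnings.warn(
                            f"unknown vdj element {el.tag!r} preserved as payload",
                            VdjmlFormatWarning,
                            stacklevel=2,
                        )
                        self.extensions.append(_payload_str(el))
                else:
                    self.extensions.append(_payload_str(el))
                el.clear()

    def close(self) -> None:
        self._stream.close()

    def __enter__(self) -> "VdjmlReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_reader(source: Source) -> VdjmlReader:
    """Open a VDJML file (plain, gzip or bzip2) for streaming reading."""
    return VdjmlReader(source)


def read_document(source: Source) -> Document:
    """Read an entire VDJML file into a :class:`~vdjml.model.Document`."""
    with open_reader(source) as reader:
        reads = list(reader)
        return Document(
            meta=reader.meta,
            reads=reads,
            version=reader.version or VDJML_VERSION,
            extensions=list(reader.extensions),
        )


# ---------------------------------------------------------------------------
# writer


class WriterClosedError(RuntimeError):
    """A read was written to an already-closed writer."""


class InvalidReadError(ValueError):
    """A read handed to the writer fails model invariants."""

    def __init__(self, violations: list[Violation]):
        super().__init__("; ".join(str(v) for v in violations))
        self.violations = violations


class VdjmlWriter:
    """Incremental VDJML writer.

    The metadata block is serialized on construction; each subsequent
    :meth:`write_read` call appends one serialized ``vdj:read`` element.
    Closing emits the trailing tags, producing a well-formed document.
    """

    def __init__(self, sink: Source, meta: Meta, generator: Optional[Generator] = None):
        if generator is not None:
            meta = Meta(
                generator=generator,
                aligners=meta.aligners,
                germline_dbs=meta.germline_dbs,
                extensions=meta.extensions,
            )
        self._meta = meta
        shell = Document(meta=meta)
        violations = validate_document(shell)
        if violations:
            raise InvalidReadError(violations)
        self._owns = isinstance(sink, (str, Path))
        self._fh = _open_for_write(sink)
        self._closed = False
        self._fh.write(b'<?xml version="1.0" encoding="UTF-8"?>\n')
        self._fh.write(
            f'<vdj:vdjml xmlns:vdj="{VDJ_NAMESPACE}" version="{VDJML_VERSION}">\n'.encode()
        )
        self._fh.write(etree.tostring(meta_to_element(meta), pretty_print=True))
        self._fh.write(b"<vdj:read_results>\n")

    def write_read(self, read: Read) -> None:
        if self._closed:
            raise WriterClosedError("writer is closed")
        shell = Document(meta=self._meta, reads=[read])
        violations = validate_document(shell)
        if violations:
            raise InvalidReadError(violations)
        self._fh.write(etree.tostring(read_to_element(read), pretty_print=True))

    def write_extension(self, payload: str) -> None:
        """Append a foreign-namespace element under ``vdj:read_results``."""
        if self._closed:
            raise WriterClosedError("writer is closed")
        self._fh.write(etree.tostring(etree.fromstring(payload)))
        self._fh.write(b"\n")

    def close(self) -> None:
        if self._closed:
            return
        self._fh.write(b"</vdj:read_results>\n</vdj:vdjml>\n")
        self._fh.flush()
        if self._owns or isinstance(self._fh, (gzip.GzipFile, bz2.BZ2File)):
            self._fh.close()
        self._closed = True

    def __enter__(self) -> "VdjmlWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_writer(sink: Source, meta: Meta, generator: Optional[Generator] = None) -> VdjmlWriter:
    """Open a VDJML writer; compression follows the sink extension (.gz/.bz2)."""
    return VdjmlWriter(sink, meta, generator)


def write_document(doc: Document, sink: Source) -> None:
    """Write a whole document through the incremental writer."""
    with open_writer(sink, doc.meta) as w:
        for read in doc.reads:
            w.write_read(read)
        for payload in doc.extensions:
            w.write_extension(payload)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """XSD violations plus model-level violations for one file."""

    xsd_errors: list[str] = field(default_factory=list)
    model_violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.xsd_errors and not self.model_violations

    def __str__(self) -> str:
        lines = [f"XSD: {e}" for e in self.xsd_errors]
        lines += [f"model: {v}" for v in self.model_violations]
        return "\n".join(lines) if lines else "valid"


def load_schema() -> etree.XMLSchema:
    """Load the VDJML 1.0 XSD shipped with the package."""
    with resources.files(__package__).joinpath("vdjml-1.0.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def validate_file(source: Source, xsd: Optional[etree.XMLSchema] = None) -> ValidationReport:
    """Validate a VDJML file against the XSD and the model invariants."""
    if xsd is None:
        xsd = load_schema()
    report = ValidationReport()
    stream = _open_for_read(source)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as e:
        report.xsd_errors.append(f"malformed XML: {e}")
        return report
    finally:
        stream.close()
    if not xsd.validate(tree):
        report.xsd_errors.extend(str(e) for e in xsd.error_log)
        return report
    if isinstance(source, (str, Path)):
        doc = read_document(source)
    else:
        source.seek(0)
        doc = read_document(source)
    report.model_violations.extend(validate_document(doc))
    return report
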