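"""SAM text format: header model, alignment records and CIGAR arithmetic.

A :class:`SamRecord` is a lossless image of one alignment line.  Optional
tags keep their type code and a typed value; integer tag types from BAM
(c, C, s, S, i, I) all canonicalize to ``i`` because SAM text has only one
integer code — round-trip equality through BAM is therefore defined on
values, not on the width codes.  Float tags are rendered with ``%g``.

CIGAR arithmetic is what projects an aligned read onto the reference:
ops M, D, N, =, X consume reference bases; M, I, S, =, X consume query
bases.  A mapped record at 1-based POS with reference span *L* covers the
canonical interval ``(rname, pos-1, pos-1+L)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, TextIO, Union

from ._streams import open_text
from .errors import FormatError
from .genome import GenomeAssembly, GenomicInterval

logger = logging.getLogger(__name__)

CIGAR_OPS = "MIDNSHP=X"
_REF_CONSUMING = frozenset("MDN=X")
_QUERY_CONSUMING = frozenset("MIS=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class Cigar:
    """Run-length encoded alignment description."""

    ops: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.ops:
            raise FormatError("empty CIGAR")
        for length, op in self.ops:
            if length < 1:
                raise FormatError(f"CIGAR op length {length} < 1")
            if op not in CIGAR_OPS:
                raise FormatError(f"unknown CIGAR op {op!r}")
        # H only at the ends; S only at the ends or just inside H
        inner = list(self.ops)
        if inner and inner[0][1] == "H":
            inner = inner[1:]
        if inner and inner[-1][1] == "H":
            inner = inner[:-1]
        for i, (_, op) in enumerate(inner):
            if op == "H":
                raise FormatError("H op allowed only at CIGAR ends")
            if op == "S" and 0 < i < len(inner) - 1:
                raise FormatError("S op allowed only at CIGAR ends")

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        if not text or text == "*":
            raise FormatError(f"cannot parse CIGAR from {text!r}")
        pos = 0
        ops: list[tuple[int, str]] = []
        for m in _CIGAR_RE.finditer(text):
            if m.start() != pos:
                raise FormatError(f"malformed CIGAR {text!r}")
            ops.append((int(m.group(1)), m.group(2)))
            pos = m.end()
        if pos != len(text):
            raise FormatError(f"malformed CIGAR {text!r}")
        return cls(tuple(ops))

    def __str__(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.ops)

    def reference_span(self) -> int:
        """Reference bases consumed (ops M, D, N, =, X)."""
        return sum(n for n, op in self.ops if op in _REF_CONSUMING)

    def query_length(self) -> int:
        """Query bases consumed (ops M, I, S, =, X); must equal len(SEQ)."""
        return sum(n for n, op in self.ops if op in _QUERY_CONSUMING)


def cigar_reference_span(c: Cigar) -> int:
    return c.reference_span()


@dataclass(frozen=True)
class SamTag:
    """One optional field TAG:TYPE:VALUE."""

    tag: str
    type: str  # A i f Z H B
    value: object  # str for A/Z/H, int, float, or (subtype, tuple) for B

    def __str__(self) -> str:
        if self.type == "f":
            return f"{self.tag}:f:{format_float(self.value)}"
        if self.type == "B":
            subtype, values = self.value
            rendered = (
                ",".join(format_float(v) for v in values)
                if subtype == "f"
                else ",".join(str(v) for v in values)
            )
            return f"{self.tag}:B:{subtype},{rendered}" if values else (
                f"{self.tag}:B:{subtype}"
            )
        return f"{self.tag}:{self.type}:{self.value}"


def format_float(v: float) -> str:
    """Render a float tag the way samtools does: %g."""
    return "%g" % v


def parse_tag(token: str) -> SamTag:
    parts = token.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2:
        raise FormatError(f"malformed tag {token!r}")
    tag, code, raw = parts
    if code in ("c", "C", "s", "S", "I"):
        code = "i"  # SAM text has a single integer type
    if code == "i":
        try:
            return SamTag(tag, "i", int(raw))
        except ValueError:
            raise FormatError(f"tag {tag}: {raw!r} is not an integer") from None
    if code == "f":
        try:
            return SamTag(tag, "f", float(raw))
        except ValueError:
            raise FormatError(f"tag {tag}: {raw!r} is not a float") from None
    if code == "A":
        if len(raw) != 1:
            raise FormatError(f"tag {tag}: A value must be one character")
        return SamTag(tag, "A", raw)
    if code in ("Z", "H"):
        return SamTag(tag, code, raw)
    if code == "B":
        items = raw.split(",")
        subtype = items[0]
        if subtype not in "cCsSiIf":
            raise FormatError(f"tag {tag}: bad B subtype {subtype!r}")
        conv = float if subtype == "f" else int
        try:
            values = tuple(conv(x) for x in items[1:])
        except ValueError:
            raise FormatError(f"tag {tag}: bad B array {raw!r}") from None
        return SamTag(tag, "B", (subtype, values))
    raise FormatError(f"tag {tag}: unknown type code {code!r}")


@dataclass(frozen=True)
class SamHeaderLine:
    """One @-line: record type plus ordered (tag, value) pairs.

    @CO lines keep their free text as a single ("", text) pair.
    """

    record_type: str  # "HD", "SQ", "RG", "PG", "CO"
    fields: tuple[tuple[str, str], ...]

    def __str__(self) -> str:
        if self.record_type == "CO":
            return "@CO\t" + self.fields[0][1]
        return "@" + self.record_type + "".join(
            f"\t{k}:{v}" for k, v in self.fields
        )

    def get(self, tag: str) -> str | None:
        for k, v in self.fields:
            if k == tag:
                return v
        return None


@dataclass(frozen=True)
class SamHeader:
    lines: tuple[SamHeaderLine, ...] = ()

    @classmethod
    def parse(cls, text_lines: Iterable[str]) -> "SamHeader":
        out: list[SamHeaderLine] = []
        for line in text_lines:
            line = line.rstrip("\n")
            if not line.startswith("@") or len(line) < 3:
                raise FormatError(f"malformed header line {line!r}")
            rtype = line[1:3]
            rest = line[4:] if len(line) > 3 else ""
            if rtype == "CO":
                out.append(SamHeaderLine("CO", (("", rest),)))
                continue
            fields = []
            for tok in rest.split("\t") if rest else []:
                if ":" not in tok:
                    raise FormatError(f"malformed header field {tok!r}")
                k, _, v = tok.partition(":")
                fields.append((k, v))
            out.append(SamHeaderLine(rtype, tuple(fields)))
        return cls(tuple(out))

    def to_text(self) -> str:
        return "".join(str(line) + "\n" for line in self.lines)

    def reference_names(self) -> tuple[str, ...]:
        return tuple(
            line.get("SN") or ""
            for line in self.lines
            if line.record_type == "SQ"
        )

    def to_assembly(self) -> GenomeAssembly:
        """Derive the bounding assembly from the @SQ SN/LN pairs."""
        pairs = []
        for line in self.lines:
            if line.record_type != "SQ":
                continue
            name, length = line.get("SN"), line.get("LN")
            if not name or length is None:
                raise FormatError("@SQ line lacks SN or LN")
            pairs.append((name, int(length)))
        return GenomeAssembly.from_pairs(pairs)


@dataclass(frozen=True)
class SamRecord:
    """One alignment: the 11 mandatory fields plus optional tags.

    ``rname``/``rnext`` are None when "*"; ``pos`` is 1-based with 0 for
    unmapped; ``seq``/``qual`` are None when "*".
    """

    qname: str
    flag: int
    rname: Optional[str]
    pos: int
    mapq: int
    cigar: Optional[Cigar]
    rnext: Optional[str]
    pnext: int
    tlen: int
    seq: Optional[str]
    qual: Optional[str]
    tags: tuple[SamTag, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.flag < 1 << 16:
            raise FormatError(f"FLAG {self.flag} outside 16-bit range")
        if not 0 <= self.mapq <= 255:
            raise FormatError(f"MAPQ {self.mapq} outside 0..255")
        if self.cigar is not None and self.seq is not None:
            if self.cigar.query_length() != len(self.seq):
                raise FormatError(
                    f"CIGAR query length {self.cigar.query_length()} != "
                    f"sequence length {len(self.seq)}"
                )
        if self.seq is not None and self.qual is not None:
            if len(self.seq) != len(self.qual):
                raise FormatError("SEQ and QUAL lengths differ")
        if self.flag & FLAG_UNMAPPED and self.rname is not None:
            logger.warning(
                "record %s has the unmapped flag but a reference name",
                self.qname,
            )

    @property
    def is_mapped(self) -> bool:
        return (
            not self.flag & FLAG_UNMAPPED
            and self.rname is not None
            and self.pos > 0
            and self.cigar is not None
        )

    def tag(self, name: str) -> SamTag | None:
        for t in self.tags:
            if t.tag == name:
                return t
        return None


def parse_sam_record(line: str, header: SamHeader | None = None) -> SamRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise FormatError(
            f"SAM record has {len(fields)} fields, need >= 11"
        )
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq = int(fields[4])
        pnext = int(fields[7])
        tlen = int(fields[8])
    except ValueError as exc:
        raise FormatError(f"non-numeric mandatory field: {exc}") from None
    rname = None if fields[2] == "*" else fields[2]
    if (
        rname is not None
        and header is not None
        and header.reference_names()
        and rname not in header.reference_names()
    ):
        logger.warning("reference %r absent from header @SQ lines", rname)
    cigar = None if fields[5] == "*" else Cigar.from_string(fields[5])
    return SamRecord(
        qname=fields[0],
        flag=flag,
        rname=rname,
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        rnext=None if fields[6] == "*" else fields[6],
        pnext=pnext,
        tlen=tlen,
        seq=None if fields[9] == "*" else fields[9],
        qual=None if fields[10] == "*" else fields[10],
        tags=tuple(parse_tag(t) for t in fields[11:]),
    )


def write_sam_record(rec: SamRecord) -> str:
    fields = [
        rec.qname,
        str(rec.flag),
        rec.rname if rec.rname is not None else "*",
        str(rec.pos),
        str(rec.mapq),
        str(rec.cigar) if rec.cigar is not None else "*",
        rec.rnext if rec.rnext is not None else "*",
        str(rec.pnext),
        str(rec.tlen),
        rec.seq if rec.seq is not None else "*",
        rec.qual if rec.qual is not None else "*",
    ]
    fields.extend(str(t) for t in rec.tags)
    return "\t".join(fields)


def sam_to_interval(rec: SamRecord) -> GenomicInterval | None:
    """Reference footprint of a mapped record; None for unmapped ones."""
    if not rec.is_mapped:
        return None
    start = rec.pos - 1
    return GenomicInterval(
        rec.rname, start, start + rec.cigar.reference_span()
    )


def read_sam(
    source: str | TextIO,
) -> tuple[SamHeader, Iterator[SamRecord]]:
    """Read the @-header eagerly; stream alignment records lazily."""
    header_lines: list[str] = []
    body: list[tuple[int, str]] = []
    with open_text(source) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if body:
                    raise FormatError("header line after records", lineno)
                header_lines.append(line)
            else:
                body.append((lineno, line))
    header = SamHeader.parse(header_lines)

    def records() -> Iterator[SamRecord]:
        for lineno, line in body:
            try:
                yield parse_sam_record(line, header)
            except FormatError as exc:
                raise FormatError(str(exc), lineno) from None

    return header, records()


def write_sam(
    header: SamHeader, records: Iterable[SamRecord], sink: str | TextIO
) -> None:
    with open_text(sink, "w") as fh:
        fh.write(header.to_text())
        for rec in records:
            fh.write(write_sam_record(rec) + "\n")
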