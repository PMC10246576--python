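"""GFF3 and GTF readers/writers (9 tab-separated columns, 1-based inclusive).

Both formats share the first eight columns; they differ in the attribute
grammar of column 9:

* GFF3: ``tag=value[,value...]`` pairs separated by ``;``, with the reserved
  characters (tab, newline, ``%``, ``;``, ``=``, ``&``, ``,``) percent-encoded
  inside values.  Only those seven escapes are decoded on parse and exactly
  those seven characters are re-encoded on write, which makes
  parse/serialize a bijection on well-formed lines.
* GTF: ``key "value";`` pairs separated by single spaces, trailing semicolon
  required (strict by design; the strictness is what makes round-trips
  testable).

Numeric score tokens are stored verbatim (``"0"`` and ``"0.0"`` are
different bytes), as are phase and strand.  Conversion to the canonical
0-based half-open interval shifts start by -1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO, Union

from ._streams import open_text
from .errors import FormatError
from .genome import GenomicInterval, UNSTRANDED

logger = logging.getLogger(__name__)

_GFF3_DECODE = {
    "%09": "\t",
    "%0A": "\n",
    "%25": "%",
    "%3B": ";",
    "%3D": "=",
    "%26": "&",
    "%2C": ",",
}
_GFF3_ENCODE = {v: k for k, v in _GFF3_DECODE.items()}
_ESCAPE_RE = re.compile("|".join(re.escape(k) for k in _GFF3_DECODE))
_RESERVED_RE = re.compile("[\t\n%;=&,]")
_GTF_PAIR_RE = re.compile(r'^(\S+) "([^"]*)";$')
_STRANDS = ("+", "-", ".", "?")
_PHASES = (".", "0", "1", "2")


def _decode(token: str) -> str:
    return _ESCAPE_RE.sub(lambda m: _GFF3_DECODE[m.group(0)], token)


def _encode(value: str) -> str:
    return _RESERVED_RE.sub(lambda m: _GFF3_ENCODE[m.group(0)], value)


@dataclass(frozen=True)
class _FeatureRecord:
    """Columns shared by GFF3 and GTF."""

    seqid: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int
    score: str  # raw token, "." for missing
    strand: str
    phase: str  # raw token, "." for missing

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"coordinate error: start {self.start} / end {self.end}"
            )
        if self.strand not in _STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.phase not in _PHASES:
            raise FormatError(f"invalid phase {self.phase!r}")


@dataclass(frozen=True)
class Gff3Record(_FeatureRecord):
    """One GFF3 feature line.

    ``attributes`` is an ordered tuple of ``(tag, values)`` pairs where
    ``values`` is the tuple of comma-separated, percent-decoded parts.
    """

    attributes: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def attribute(self, tag: str) -> tuple[str, ...] | None:
        for t, v in self.attributes:
            if t == tag:
                return v
        return None


@dataclass(frozen=True)
class GtfRecord(_FeatureRecord):
    """One GTF feature line; ``attributes`` is an ordered tuple of
    ``(key, value)`` pairs from the ``key "value";`` grammar."""

    attributes: tuple[tuple[str, str], ...] = ()

    def attribute(self, key: str) -> str | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return None


def _split_columns(line: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise FormatError(f"expected 9 tab-separated columns, got {len(fields)}")
    return fields


def _parse_common(fields: list[str]) -> dict:
    try:
        start = int(fields[3])
        end = int(fields[4])
    except ValueError:
        raise FormatError(
            f"coordinates {fields[3]!r}/{fields[4]!r} are not integers"
        ) from None
    return dict(
        seqid=fields[0],
        source=fields[1],
        type=fields[2],
        start=start,
        end=end,
        score=fields[5],
        strand=fields[6],
        phase=fields[7],
    )


def parse_gff3_record(line: str) -> Gff3Record:
    fields = _split_columns(line)
    common = _parse_common(fields)
    attrs: list[tuple[str, tuple[str, ...]]] = []
    col9 = fields[8]
    if col9 != ".":
        for pair in col9.split(";"):
            if "=" not in pair:
                raise FormatError(
                    f"attribute-syntax error: {pair!r} lacks '='"
                )
            tag, _, raw = pair.partition("=")
            if not tag:
                raise FormatError(f"attribute-syntax error: empty tag in {pair!r}")
            attrs.append((_decode(tag), tuple(_decode(p) for p in raw.split(","))))
    rec = Gff3Record(attributes=tuple(attrs), **common)
    if rec.type == "CDS" and rec.phase == ".":
        logger.warning("CDS feature on %s:%d has no phase", rec.seqid, rec.start)
    return rec


def write_gff3_record(rec: Gff3Record) -> str:
    if rec.attributes:
        col9 = ";".join(
            _encode(tag) + "=" + ",".join(_encode(p) for p in parts)
            for tag, parts in rec.attributes
        )
    else:
        col9 = "."
    return "\t".join(
        (
            rec.seqid,
            rec.source,
            rec.type,
            str(rec.start),
            str(rec.end),
            rec.score,
            rec.strand,
            rec.phase,
            col9,
        )
    )


def parse_gtf_record(line: str) -> GtfRecord:
    fields = _split_columns(line)
    common = _parse_common(fields)
    attrs: list[tuple[str, str]] = []
    col9 = fields[8]
    if col9 != ".":
        for chunk in col9.split("; "):
            if not chunk.endswith(";"):
                chunk += ";"  # the split removed it for all but the last
            m = _GTF_PAIR_RE.match(chunk)
            if m is None:
                raise FormatError(
                    f'attribute-syntax error: {chunk!r} does not match '
                    f'key "value";'
                )
            attrs.append((m.group(1), m.group(2)))
        if not col9.endswith(";"):
            raise FormatError("attribute-syntax error: missing trailing ';'")
    return GtfRecord(attributes=tuple(attrs), **common)


def write_gtf_record(rec: GtfRecord) -> str:
    if rec.attributes:
        col9 = " ".join(f'{k} "{v}";' for k, v in rec.attributes)
    else:
        col9 = "."
    return "\t".join(
        (
            rec.seqid,
            rec.source,
            rec.type,
            str(rec.start),
            str(rec.end),
            rec.score,
            rec.strand,
            rec.phase,
            col9,
        )
    )


def feature_to_interval(rec: _FeatureRecord) -> GenomicInterval:
    """1-based inclusive -> 0-based half-open: (start-1, end)."""
    strand = rec.strand if rec.strand in ("+", "-") else UNSTRANDED
    return GenomicInterval(rec.seqid, rec.start - 1, rec.end, strand)


def _read_features(source, parse, kind: str) -> Iterator:
    with open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            if stripped.startswith("#"):
                yield stripped  # directives/comments pass through verbatim
                continue
            try:
                yield parse(stripped)
            except FormatError as exc:
                raise FormatError(f"{kind}: {exc}", lineno) from None


def read_gff3(source: str | TextIO) -> Iterator[Union[Gff3Record, str]]:
    """Stream a GFF3 file; ``#``-prefixed directive lines are yielded verbatim."""
    return _read_features(source, parse_gff3_record, "GFF3")


def read_gtf(source: str | TextIO) -> Iterator[Union[GtfRecord, str]]:
    return _read_features(source, parse_gtf_record, "GTF")


def _write_features(records: Iterable, sink, write) -> None:
    with open_text(sink, "w") as fh:
        for rec in records:
            fh.write(rec if isinstance(rec, str) else write(rec))
            fh.write("\n")


def write_gff3(records: Iterable[Union[Gff3Record, str]], sink: str | TextIO) -> None:
    _write_features(records, sink, write_gff3_record)


def write_gtf(records: Iterable[Union[GtfRecord, str]], sink: str | TextIO) -> None:
    _write_features(records, sink, write_gtf_record)
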