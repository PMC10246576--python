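"""VCF 4.x reader/writer and variant-level primitives.

The reader streams records lazily and keeps every token verbatim, so
serialization reproduces the input byte-for-byte: meta lines are stored as
raw strings (with structured views for INFO/FORMAT/FILTER/contig lines),
INFO values keep their raw tokens and are typed only on access, and
per-sample genotype columns are kept as raw strings.  Unknown meta-line
keys pass through untouched.

Variant classification for the Ti/Tv use case lives here:
:func:`classify_snv` labels a (ref, alt) pair as transition (within purines
{A, G} or within pyrimidines {C, T}), transversion (any other single-base
substitution) or not an SNV (indels, MNVs, symbolic alleles, ref == alt).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from ._streams import open_text
from .errors import FormatError, SymbolicAlleleError
from .genome import GenomicInterval

TRANSITION = "transition"
TRANSVERSION = "transversion"
NOT_SNV = "not_snv"

_BASES = frozenset("ACGT")
_TRANSITION_PAIRS = frozenset(
    {frozenset({"A", "G"}), frozenset({"C", "T"})}
)
_ALLELE_RE = re.compile(r"^[ACGTNacgtn]+$")
_STRUCTURED_RE = re.compile(r"^##(?P<key>[^=]+)=<(?P<body>.*)>$")
_REQUIRED_COLUMNS = (
    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
)


def _parse_structured_body(body: str) -> dict[str, str]:
    """Parse `ID=DP,Number=1,Type=Integer,Description="..."` bodies."""
    out: dict[str, str] = {}
    i = 0
    n = len(body)
    while i < n:
        j = body.index("=", i)
        key = body[i:j]
        i = j + 1
        if i < n and body[i] == '"':
            j = body.index('"', i + 1)
            out[key] = body[i + 1 : j]
            i = j + 1
        else:
            j = body.find(",", i)
            j = n if j == -1 else j
            out[key] = body[i:j]
            i = j
        if i < n and body[i] == ",":
            i += 1
    return out


@dataclass(frozen=True)
class VcfHeader:
    """All ``##`` meta lines (verbatim, order preserved) plus the sample list.

    ``info``, ``formats``, ``filters`` and ``contigs`` are structured views
    keyed by ID; the raw lines remain authoritative for writing.
    """

    meta_lines: tuple[str, ...]
    samples: tuple[str, ...] = ()
    info: dict[str, dict[str, str]] = field(default_factory=dict, compare=False)
    formats: dict[str, dict[str, str]] = field(default_factory=dict, compare=False)
    filters: dict[str, dict[str, str]] = field(default_factory=dict, compare=False)
    contigs: dict[str, dict[str, str]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.meta_lines or not self.meta_lines[0].startswith(
            "##fileformat="
        ):
            raise FormatError("first header line must be ##fileformat=")
        views = {"INFO": self.info, "FORMAT": self.formats,
                 "FILTER": self.filters, "contig": self.contigs}
        for line in self.meta_lines:
            m = _STRUCTURED_RE.match(line)
            if m and m.group("key") in views:
                fields = _parse_structured_body(m.group("body"))
                if "ID" in fields:
                    views[m.group("key")][fields["ID"]] = fields

    @property
    def fileformat(self) -> str:
        return self.meta_lines[0][len("##fileformat="):]

    def column_line(self) -> str:
        cols = list(_REQUIRED_COLUMNS)
        if self.samples:
            cols.append("FORMAT")
            cols.extend(self.samples)
        return "\t".join(cols)


@dataclass(frozen=True)
class VcfRecord:
    """One VCF data line; tokens kept raw for byte-exact writing."""

    chrom: str
    pos: int  # 1-based
    id: str  # "." for missing
    ref: str
    alt: tuple[str, ...]  # alternate alleles, may be (".",)
    qual: str  # raw token
    filter: str  # raw token: "PASS", "." or ;-joined IDs
    info: tuple[tuple[str, str | None], ...]  # (key, raw value); None = flag
    format_keys: tuple[str, ...] | None = None
    sample_values: tuple[str, ...] = ()  # raw per-sample columns

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"POS {self.pos} < 1")
        if not self.ref:
            raise FormatError("empty REF allele")

    def info_value(self, key: str) -> str | None:
        for k, v in self.info:
            if k == key:
                return v
        return None

    def typed_info(self, header: VcfHeader) -> dict[str, object]:
        """Type INFO values per the header's Type/Number declarations.

        Flags map to True; Integer/Float values are converted (lists for
        Number != 1); everything else stays a string.
        """
        out: dict[str, object] = {}
        for key, raw in self.info:
            if raw is None:
                out[key] = True
                continue
            decl = header.info.get(key, {})
            typ = decl.get("Type", "String")
            conv = {"Integer": int, "Float": float}.get(typ, str)
            parts = raw.split(",")
            try:
                vals = [conv(p) for p in parts]
            except ValueError:
                vals = parts  # malformed per header; raw tokens win
            out[key] = vals[0] if len(vals) == 1 and decl.get("Number") == "1" else (
                vals if len(vals) > 1 else vals[0]
            )
        return out


def _parse_info(token: str) -> tuple[tuple[str, str | None], ...]:
    if token == ".":
        return ()
    out = []
    for chunk in token.split(";"):
        if "=" in chunk:
            k, _, v = chunk.partition("=")
            out.append((k, v))
        else:
            out.append((chunk, None))
    return tuple(out)


def parse_vcf_record(line: str, header: VcfHeader, lineno: int | None = None) -> VcfRecord:
    fields = line.rstrip("\n").split("\t")
    n_fixed = 8
    expected = n_fixed + (1 + len(header.samples) if header.samples else 0)
    if len(fields) != expected:
        raise FormatError(
            f"expected {expected} columns, got {len(fields)}", lineno
        )
    try:
        pos = int(fields[1])
    except ValueError:
        raise FormatError(f"POS {fields[1]!r} is not an integer", lineno) from None
    alt = tuple(fields[4].split(","))
    try:
        return VcfRecord(
            chrom=fields[0],
            pos=pos,
            id=fields[2],
            ref=fields[3],
            alt=alt,
            qual=fields[5],
            filter=fields[6],
            info=_parse_info(fields[7]),
            format_keys=tuple(fields[8].split(":")) if header.samples else None,
            sample_values=tuple(fields[9:]),
        )
    except FormatError as exc:
        raise FormatError(str(exc), lineno) from None


def write_vcf_record(rec: VcfRecord) -> str:
    info = (
        ";".join(k if v is None else f"{k}={v}" for k, v in rec.info)
        if rec.info
        else "."
    )
    fields = [
        rec.chrom,
        str(rec.pos),
        rec.id,
        rec.ref,
        ",".join(rec.alt),
        rec.qual,
        rec.filter,
        info,
    ]
    if rec.format_keys is not None:
        fields.append(":".join(rec.format_keys))
        fields.extend(rec.sample_values)
    return "\t".join(fields)


def read_vcf(
    source: str | TextIO,
) -> tuple[VcfHeader, Iterator[VcfRecord]]:
    """Read the header eagerly, then stream records lazily.

    The returned iterator keeps the stream open until exhausted; each
    record round-trips byte-exactly through :func:`write_vcf_record`.
    """
    meta: list[str] = []
    samples: tuple[str, ...] = ()
    header: VcfHeader | None = None
    # header is consumed eagerly so errors surface before iteration starts
    with open_text(source) as fh:
        lines = iter(enumerate(fh, 1))
        for lineno, raw in lines:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if not meta and not line.startswith("##fileformat="):
                    raise FormatError(
                        "missing-header error: file must start with "
                        "##fileformat=",
                        lineno,
                    )
                meta.append(line)
            elif line.startswith("#CHROM"):
                cols = line.split("\t")
                if tuple(cols[:8]) != _REQUIRED_COLUMNS:
                    raise FormatError(
                        f"malformed column header line: {line!r}", lineno
                    )
                if len(cols) > 8:
                    if cols[8] != "FORMAT":
                        raise FormatError(
                            "9th column header must be FORMAT", lineno
                        )
                    samples = tuple(cols[9:])
                header = VcfHeader(tuple(meta), samples)
                break
            else:
                raise FormatError(
                    "missing-header error: data line before #CHROM header",
                    lineno,
                )
        if header is None:
            raise FormatError("missing-header error: no #CHROM line found")
        body = [(lineno, ln.rstrip("\n")) for lineno, ln in lines]

    def records() -> Iterator[VcfRecord]:
        for lineno, line in body:
            if line:
                yield parse_vcf_record(line, header, lineno)

    return header, records()


def read_vcf_stream(fh: TextIO) -> tuple[VcfHeader, Iterator[VcfRecord]]:
    """Fully lazy variant of :func:`read_vcf` over an already-open stream.

    Record parsing happens on demand, so files larger than memory can be
    processed one record at a time.
    """
    meta: list[str] = []
    header: VcfHeader | None = None
    lines = iter(enumerate(fh, 1))
    for lineno, raw in lines:
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            if not meta and not line.startswith("##fileformat="):
                raise FormatError("missing-header error", lineno)
            meta.append(line)
        elif line.startswith("#CHROM"):
            cols = line.split("\t")
            samples = tuple(cols[9:]) if len(cols) > 8 else ()
            header = VcfHeader(tuple(meta), samples)
            break
        else:
            raise FormatError("missing-header error: data before #CHROM", lineno)
    if header is None:
        raise FormatError("missing-header error: no #CHROM line found")

    def records() -> Iterator[VcfRecord]:
        for lineno, raw in lines:
            line = raw.rstrip("\n")
            if line:
                yield parse_vcf_record(line, header, lineno)

    return header, records()


def write_vcf(
    header: VcfHeader, records: Iterable[VcfRecord], sink: str | TextIO
) -> None:
    with open_text(sink, "w") as fh:
        for line in header.meta_lines:
            fh.write(line + "\n")
        fh.write(header.column_line() + "\n")
        for rec in records:
            fh.write(write_vcf_record(rec) + "\n")


def vcf_to_interval(rec: VcfRecord) -> GenomicInterval:
    """Project a record to its reference-genome footprint.

    The interval is ``(chrom, pos-1, pos-1+len(ref))``; when an END INFO
    key is present (symbolic SVs carry one) it overrides the interval end.
    Symbolic REF alleles raise :class:`SymbolicAlleleError`.
    """
    if not _ALLELE_RE.match(rec.ref):
        raise SymbolicAlleleError(
            f"REF allele {rec.ref!r} at {rec.chrom}:{rec.pos} is not a "
            "literal sequence"
        )
    start = rec.pos - 1
    end = start + len(rec.ref)
    raw_end = rec.info_value("END")
    if raw_end is not None:
        end = int(raw_end)
    return GenomicInterval(rec.chrom, start, end)


def classify_snv(ref: str, alt: str) -> str:
    """Classify one (ref, alt) allele pair.

    Transition iff both are single bases with {ref, alt} within the purines
    {A, G} or within the pyrimidines {C, T}; transversion for every other
    single-base substitution; NOT_SNV for indels, MNVs, symbolic alleles,
    N-containing alleles and ref == alt.  Symmetric in its arguments.
    """
    r, a = ref.upper(), alt.upper()
    if len(r) != 1 or len(a) != 1 or r not in _BASES or a not in _BASES:
        return NOT_SNV
    if r == a:
        return NOT_SNV
    if frozenset({r, a}) in _TRANSITION_PAIRS:
        return TRANSITION
    return TRANSVERSION
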