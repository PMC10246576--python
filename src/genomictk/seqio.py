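"""FASTA and FASTQ streaming readers and writers.

Both readers are lazy generators.  FASTA multi-line sequences are
concatenated, so the original line wrapping is not preserved — the writer
re-wraps at a caller-chosen width (round-trips are exact when re-wrapped at
the source width, and exact modulo wrapping otherwise).  FASTQ is strict
four-line-per-record: multi-line FASTQ is ambiguous (``@`` may begin a
quality line) and is rejected; the optional repeated identifier after ``+``
is dropped on read and never written.

Sequence alphabets are not validated: this module is transport, not
biology.  Quality strings are carried as-is (Phred+33 presumed, never
decoded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from ._streams import open_text
from .errors import FormatError


@dataclass(frozen=True)
class FastaRecord:
    """identifier = first whitespace-delimited header token; description =
    the rest of the header (empty when absent)."""

    identifier: str
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FormatError("empty FASTA identifier")

    @property
    def header(self) -> str:
        return (
            f"{self.identifier} {self.description}"
            if self.description
            else self.identifier
        )


@dataclass(frozen=True)
class FastqRecord:
    identifier: str
    description: str = ""
    sequence: str = ""
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise FormatError("empty FASTQ identifier")
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)} for {self.identifier!r}"
            )

    @property
    def header(self) -> str:
        return (
            f"{self.identifier} {self.description}"
            if self.description
            else self.identifier
        )


def _split_header(line: str) -> tuple[str, str]:
    parts = line.split(None, 1)
    if not parts:
        raise FormatError("empty header line")
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_fasta(source: str | TextIO) -> Iterator[FastaRecord]:
    """Stream records; data before the first ``>`` is a leading-garbage error."""
    with open_text(source) as fh:
        identifier: str | None = None
        description = ""
        chunks: list[str] = []
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if identifier is not None:
                    yield FastaRecord(identifier, description, "".join(chunks))
                identifier, description = _split_header(line[1:])
                chunks = []
            else:
                if identifier is None:
                    raise FormatError(
                        "leading-garbage error: sequence data before the "
                        "first '>' header",
                        lineno,
                    )
                chunks.append(line.strip())
        if identifier is not None:
            yield FastaRecord(identifier, description, "".join(chunks))


def write_fasta(
    records: Iterable[FastaRecord],
    sink: str | TextIO,
    wrap: int | None = None,
) -> None:
    """Write records, wrapping sequence lines at *wrap* characters if given."""
    if wrap is not None and wrap < 1:
        raise ValueError("wrap must be a positive integer or None")
    with open_text(sink, "w") as fh:
        for rec in records:
            fh.write(">" + rec.header + "\n")
            seq = rec.sequence
            if not seq:
                continue
            if wrap is None:
                fh.write(seq + "\n")
            else:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")


def read_fastq(source: str | TextIO) -> Iterator[FastqRecord]:
    """Stream strict 4-line records (@header, sequence, +, quality)."""
    with open_text(source) as fh:
        lines = iter(enumerate(fh, 1))
        while True:
            group = []
            for _ in range(4):
                item = next(lines, None)
                if item is None:
                    break
                group.append((item[0], item[1].rstrip("\n")))
            if not group:
                return
            if len(group) < 4:
                raise FormatError(
                    "truncated FASTQ record", group[0][0]
                )
            (l1, head), (l2, seq), (l3, plus), (l4, qual) = group
            if not head.startswith("@"):
                raise FormatError(
                    f"expected '@' header, got {head!r}", l1
                )
            if not plus.startswith("+"):
                raise FormatError(
                    f"expected '+' separator, got {plus!r}", l3
                )
            identifier, description = _split_header(head[1:])
            if len(seq) != len(qual):
                raise FormatError(
                    f"length-mismatch error: {len(seq)} sequence vs "
                    f"{len(qual)} quality characters",
                    l4,
                )
            yield FastqRecord(identifier, description, seq, qual)


def write_fastq(records: Iterable[FastqRecord], sink: str | TextIO) -> None:
    with open_text(sink, "w") as fh:
        for rec in records:
            fh.write(
                f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n"
            )
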