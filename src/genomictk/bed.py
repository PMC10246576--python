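"""BED reader/writer: 3 to 12 tab-separated columns, 0-based half-open.

BED sub-dialects (BED3..BED12) are treated as a column-prefix family: the
first three columns are typed, the remaining optional columns are validated
where the standard constrains them (score range, strand alphabet, block
consistency) but stored verbatim so that serialization reproduces the input
line byte-for-byte.  Track/browser and comment lines are preserved as opaque
pass-through lines by the file-level reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO, Union

from ._streams import open_text
from .errors import FormatError
from .genome import GenomicInterval, UNSTRANDED

_MAX_COLUMNS = 12


@dataclass(frozen=True)
class BedRecord:
    """One BED line: chrom, chrom_start, chrom_end plus verbatim extras.

    ``extra`` holds columns 4..12 exactly as they appeared (a prefix of the
    BED12 column order: name, score, strand, thickStart, thickEnd, itemRgb,
    blockCount, blockSizes, blockStarts).
    """

    chrom: str
    chrom_start: int
    chrom_end: int
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.chrom_start < 0 or self.chrom_start >= self.chrom_end:
            raise FormatError(
                f"invalid BED coordinates {self.chrom_start}..{self.chrom_end}"
            )
        if len(self.extra) > _MAX_COLUMNS - 3:
            raise FormatError("more than 12 BED columns")

    @property
    def name(self) -> str | None:
        return self.extra[0] if len(self.extra) >= 1 else None

    @property
    def score(self) -> int | None:
        return int(self.extra[1]) if len(self.extra) >= 2 else None

    @property
    def strand(self) -> str | None:
        return self.extra[2] if len(self.extra) >= 3 else None


def parse_bed_line(line: str) -> BedRecord:
    """Parse one data line; its serialization reproduces the input exactly."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"BED line has {len(fields)} columns, need >= 3")
    if len(fields) > _MAX_COLUMNS:
        raise FormatError(f"BED line has {len(fields)} columns, max is 12")
    chrom = fields[0]
    if not chrom:
        raise FormatError("column 1 (chrom): empty name")
    try:
        start = int(fields[1])
    except ValueError:
        raise FormatError(
            f"column 2 (chromStart): {fields[1]!r} is not an integer"
        ) from None
    try:
        end = int(fields[2])
    except ValueError:
        raise FormatError(
            f"column 3 (chromEnd): {fields[2]!r} is not an integer"
        ) from None
    if start < 0 or start >= end:
        raise FormatError(f"coordinate error: start {start} >= end {end}")
    extra = tuple(fields[3:])
    if len(extra) >= 2:
        try:
            score = int(extra[1])
        except ValueError:
            raise FormatError(
                f"column 5 (score): {extra[1]!r} is not an integer"
            ) from None
        if not 0 <= score <= 1000:
            raise FormatError(f"column 5 (score): {score} outside 0..1000")
    if len(extra) >= 3 and extra[2] not in ("+", "-", "."):
        raise FormatError(f"column 6 (strand): invalid value {extra[2]!r}")
    if len(extra) >= 9:
        try:
            n_blocks = int(extra[6])
        except ValueError:
            raise FormatError(
                f"column 10 (blockCount): {extra[6]!r} is not an integer"
            ) from None
        sizes = [t for t in extra[7].rstrip(",").split(",") if t]
        starts = [t for t in extra[8].rstrip(",").split(",") if t]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(
                f"blockSizes/blockStarts counts ({len(sizes)}/{len(starts)}) "
                f"differ from blockCount {n_blocks}"
            )
    return BedRecord(chrom, start, end, extra)


def write_bed_record(rec: BedRecord) -> str:
    """Serialize a record; inverse of :func:`parse_bed_line`."""
    return "\t".join(
        (rec.chrom, str(rec.chrom_start), str(rec.chrom_end), *rec.extra)
    )


def bed_to_interval(rec: BedRecord) -> GenomicInterval:
    """BED is already 0-based half-open; the strand column passes through."""
    return GenomicInterval(
        rec.chrom, rec.chrom_start, rec.chrom_end, rec.strand or UNSTRANDED
    )


def read_bed(
    source: str | TextIO,
) -> Iterator[Union[BedRecord, str]]:
    """Stream a BED file.

    Yields :class:`BedRecord` for data lines and raw strings (without the
    trailing newline) for comment/track/browser lines, so that writing the
    stream back preserves the file verbatim.
    """
    with open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            if stripped.startswith(("#", "track", "browser")):
                yield stripped
                continue
            try:
                yield parse_bed_line(stripped)
            except FormatError as exc:
                raise FormatError(str(exc), lineno) from None


def write_bed(
    records: Iterable[Union[BedRecord, str]], sink: str | TextIO
) -> None:
    with open_text(sink, "w") as fh:
        for rec in records:
            fh.write(rec if isinstance(rec, str) else write_bed_record(rec))
            fh.write("\n")
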