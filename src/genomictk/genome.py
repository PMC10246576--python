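"""The genome-bounded interval model.

Every interval in genomictk lives on a named assembled sequence (chromosome,
scaffold or contig) and uses 0-based half-open coordinates.  A
:class:`GenomeAssembly` is the universe that bounds all intervals: validation
checks that a sequence name exists and that ``end`` does not run past the
sequence length.  Coordinate conversions for 1-based formats (GFF3, GTF, WIG,
VCF, SAM) happen only at the I/O boundary; everything in memory is 0-based
half-open.

Empty intervals are unrepresentable (``start < end`` strictly); empty results
of set operations are empty collections.  Strand is carried as metadata and
never partitions interval-set algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import (
    DegenerateIntervalError,
    IntervalBoundsError,
    UnknownSequenceError,
)

#: Allowed strand markers: forward, reverse, unstranded.
FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."
_STRANDS = frozenset({FORWARD, REVERSE, UNSTRANDED})


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered map of sequence names to lengths in base pairs.

    The order of sequences is preserved and defines the sort order of
    multi-sequence outputs (e.g. of :meth:`IntervalSet.complement`).
    """

    sequences: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        lengths: dict[str, int] = {}
        for name, length in self.sequences:
            if not name:
                raise ValueError("sequence names must be non-empty")
            if name in lengths:
                raise ValueError(f"duplicate sequence name: {name!r}")
            if length < 1:
                raise ValueError(f"sequence {name!r} has length {length} < 1")
            lengths[name] = length
        object.__setattr__(self, "_lengths", lengths)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeAssembly":
        return cls(tuple((str(n), int(s)) for n, s in pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def length_of(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise UnknownSequenceError(
                f"sequence {name!r} is not part of the assembly"
            ) from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A sequence-anchored, 0-based half-open integer interval.

    ``start`` is inclusive, ``end`` exclusive, and ``start < end`` always
    holds.  ``strand`` is one of ``"+"``, ``"-"`` or ``"."`` and is metadata
    only.  The ordering key is ``(seq_name, start, end)`` so that sorting a
    list of intervals yields the canonical output order.
    """

    seq_name: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DegenerateIntervalError(
                f"negative start {self.start} on {self.seq_name}"
            )
        if self.start >= self.end:
            raise DegenerateIntervalError(
                f"degenerate interval [{self.start}, {self.end}) on "
                f"{self.seq_name}: start must be < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def validate_interval(iv: GenomicInterval, asm: GenomeAssembly) -> GenomicInterval:
    """Return *iv* unchanged if it fits inside *asm*; raise otherwise.

    Idempotent and side-effect free.  Raises :class:`UnknownSequenceError`
    when the sequence name is absent and :class:`IntervalBoundsError` when
    the interval runs past the end of its sequence.  (Degenerate intervals
    cannot be constructed in the first place.)
    """
    length = asm.length_of(iv.seq_name)
    if iv.end > length:
        raise IntervalBoundsError(
            f"interval [{iv.start}, {iv.end}) exceeds length {length} of "
            f"sequence {iv.seq_name!r}"
        )
    return iv


def interval_length(iv: GenomicInterval) -> int:
    """Number of bases covered by *iv* (``end - start``)."""
    return iv.end - iv.start


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base.

    Half-open semantics: abutting intervals (``a.end == b.start``) do not
    overlap, and intervals on different sequences never overlap.
    """
    return a.seq_name == b.seq_name and a.start < b.end and b.start < a.end
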