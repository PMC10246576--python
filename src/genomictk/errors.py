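"""Exception hierarchy shared by all genomictk modules.

Data errors raised while parsing carry an optional line number so that CLI
diagnostics can point at the offending record.
"""

from __future__ import annotations


class GenomicsError(Exception):
    """Base class for all genomictk errors."""


class UnknownSequenceError(GenomicsError):
    """An interval or record refers to a sequence absent from the assembly."""


class IntervalBoundsError(GenomicsError):
    """An interval end exceeds the length of its assembled sequence."""


class DegenerateIntervalError(GenomicsError):
    """An interval with start >= end; empty intervals are unrepresentable."""


class AssemblyMismatchError(GenomicsError):
    """A binary set operation was given sets over different assemblies."""


class FormatError(GenomicsError):
    """A malformed line or record in one of the supported file formats."""

    def __init__(self, message: str, line_number: int | None = None) -> None:
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class BgzfError(FormatError):
    """Malformed BGZF container (bad magic, missing BC subfield, truncation)."""


class CrcMismatchError(BgzfError):
    """Stored CRC32 of a BGZF block disagrees with the recomputed value."""


class SymbolicAlleleError(GenomicsError):
    """A VCF REF allele is not a literal sequence, so no interval exists."""
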