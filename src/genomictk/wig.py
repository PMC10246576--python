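"""WIG (wiggle) reader/writer for fixedStep and variableStep sections.

WIG positions are 1-based; parsed values carry the canonical 0-based start.
Each :class:`WigValue` remembers its declaration context (fixedStep with its
step, or variableStep) and its span, so a parsed file can be re-serialized.
The writer emits a canonical form: declaration lines always carry an
explicit ``span=``, fixedStep declarations list ``chrom``, ``start``,
``step``, ``span`` in that order, and variableStep value lines are
single-space separated.  ``parse(write(values))`` is exact for any value
list; ``write(parse(text))`` is exact on canonical files.

Value tokens are stored verbatim so ``1`` and ``1.0`` survive a round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from ._streams import open_text
from .errors import FormatError
from .genome import GenomicInterval

FIXED = "fixedStep"
VARIABLE = "variableStep"


@dataclass(frozen=True)
class WigValue:
    """One expanded wiggle value: *span* bases starting at 0-based *start*."""

    chrom: str
    start: int  # canonical 0-based
    span: int
    value: str  # raw token; use float_value for arithmetic
    mode: str = VARIABLE  # FIXED or VARIABLE
    step: int | None = None  # fixedStep only

    def __post_init__(self) -> None:
        if self.span < 1:
            raise FormatError(f"span {self.span} < 1")
        if self.mode not in (FIXED, VARIABLE):
            raise FormatError(f"invalid WIG mode {self.mode!r}")
        if self.mode == FIXED and (self.step is None or self.step < 1):
            raise FormatError("fixedStep values need a positive step")
        float(self.value)  # must be numeric

    @property
    def float_value(self) -> float:
        return float(self.value)


def wig_to_interval(v: WigValue) -> GenomicInterval:
    return GenomicInterval(v.chrom, v.start, v.start + v.span)


def _parse_declaration(line: str, lineno: int) -> dict[str, str]:
    tokens = line.split()
    out: dict[str, str] = {"mode": tokens[0]}
    for tok in tokens[1:]:
        if "=" not in tok:
            raise FormatError(f"malformed declaration token {tok!r}", lineno)
        key, _, val = tok.partition("=")
        out[key] = val
    if "chrom" not in out:
        raise FormatError("declaration lacks chrom=", lineno)
    return out


def read_wig(source: str | TextIO) -> list[WigValue]:
    """Expand a WIG stream to explicit (chrom, start, span, value) tuples.

    Track lines are skipped; a value line before any declaration raises a
    declaration-missing error.
    """
    values: list[WigValue] = []
    mode: str | None = None
    chrom = ""
    span = 1
    step = 1
    next_start = 0  # 0-based, fixedStep cursor
    with open_text(source) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(("track", "browser")):
                continue
            if line.startswith((FIXED, VARIABLE)):
                decl = _parse_declaration(line, lineno)
                mode = decl["mode"]
                chrom = decl["chrom"]
                span = int(decl.get("span", "1"))
                if span < 1:
                    raise FormatError(f"span {span} < 1", lineno)
                if mode == FIXED:
                    if "start" not in decl or "step" not in decl:
                        raise FormatError(
                            "fixedStep declaration lacks start= or step=", lineno
                        )
                    next_start = int(decl["start"]) - 1
                    step = int(decl["step"])
                    if step < 1:
                        raise FormatError(f"step {step} < 1", lineno)
                    if span > step:
                        raise FormatError(
                            f"span {span} exceeds step {step}", lineno
                        )
                continue
            if mode is None:
                raise FormatError(
                    "value line before any fixedStep/variableStep declaration",
                    lineno,
                )
            if mode == FIXED:
                if len(line.split()) != 1:
                    raise FormatError(
                        f"fixedStep value line has extra fields: {line!r}", lineno
                    )
                values.append(
                    WigValue(chrom, next_start, span, line, FIXED, step)
                )
                next_start += step
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"variableStep line needs 'pos value': {line!r}", lineno
                    )
                pos = int(parts[0])
                if pos < 1:
                    raise FormatError(f"position {pos} < 1", lineno)
                values.append(WigValue(chrom, pos - 1, span, parts[1], VARIABLE))
    return values


def write_wig(values: Iterable[WigValue], sink: str | TextIO) -> None:
    """Serialize values, opening a new section whenever the declaration
    context (mode, chrom, span, step or fixedStep continuity) changes."""
    with open_text(sink, "w") as fh:
        ctx: tuple | None = None
        next_start = 0
        for v in values:
            if v.mode == FIXED:
                need_decl = (
                    ctx != (FIXED, v.chrom, v.span, v.step)
                    or v.start != next_start
                )
                if need_decl:
                    fh.write(
                        f"fixedStep chrom={v.chrom} start={v.start + 1} "
                        f"step={v.step} span={v.span}\n"
                    )
                    ctx = (FIXED, v.chrom, v.span, v.step)
                fh.write(f"{v.value}\n")
                next_start = v.start + (v.step or 1)
            else:
                if ctx != (VARIABLE, v.chrom, v.span):
                    fh.write(f"variableStep chrom={v.chrom} span={v.span}\n")
                    ctx = (VARIABLE, v.chrom, v.span)
                fh.write(f"{v.start + 1} {v.value}\n")
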