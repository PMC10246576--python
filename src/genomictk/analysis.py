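"""Interval-level analyses: breadth of coverage and Ti/Tv summaries.

Breadth of coverage of a target set by aligned reads is computed entirely
with interval algebra: reads are projected to their reference footprints,
merged, and intersected with each merged target interval — no per-base
array is ever materialized, so genome-scale inputs cost only the number of
intervals involved.

The transition/transversion summary classifies every (REF, ALT) allele pair
of an SNV (one classification per alternate allele of a multi-allelic
record) and attributes it to every stratum whose region set overlaps the
variant's interval under half-open semantics.  Strata with zero
transversions report an undefined (None) ratio, never infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .errors import SymbolicAlleleError
from .genome import GenomicInterval
from .rbtree import IntervalSet
from .sam import (
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    SamRecord,
    sam_to_interval,
)
from .vcf import NOT_SNV, TRANSITION, VcfRecord, classify_snv, vcf_to_interval


@dataclass(frozen=True)
class IntervalCoverage:
    """Coverage of one merged target interval."""

    interval: GenomicInterval
    covered: int

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def breadth(self) -> float:
        return self.covered / self.length


@dataclass(frozen=True)
class CoverageSummary:
    """Per-target and total breadth of coverage."""

    per_interval: tuple[IntervalCoverage, ...]

    @property
    def total_covered(self) -> int:
        return sum(c.covered for c in self.per_interval)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.per_interval)

    @property
    def total_breadth(self) -> float:
        return self.total_covered / self.total_length if self.total_length else 0.0

    def to_table(self) -> str:
        """Tab-separated table with a header line and a trailing total row."""
        lines = ["#chrom\tstart\tend\tcovered\tlength\tbreadth"]
        for c in self.per_interval:
            iv = c.interval
            lines.append(
                f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{c.covered}\t"
                f"{c.length}\t{c.breadth:.6g}"
            )
        lines.append(
            f"#total\t.\t.\t{self.total_covered}\t{self.total_length}\t"
            f"{self.total_breadth:.6g}"
        )
        return "\n".join(lines) + "\n"


def coverage(
    targets: IntervalSet,
    reads: Iterable[SamRecord],
    include_secondary: bool = False,
    include_supplementary: bool = False,
) -> CoverageSummary:
    """Breadth of coverage of the merged *targets* by mapped reads.

    Unmapped reads never contribute; secondary (flag 0x100) and
    supplementary (0x800) alignments are excluded by default.
    """
    skip_mask = (0 if include_secondary else FLAG_SECONDARY) | (
        0 if include_supplementary else FLAG_SUPPLEMENTARY
    )
    footprints = []
    for rec in reads:
        if rec.flag & skip_mask:
            continue
        iv = sam_to_interval(rec)
        if iv is not None:
            footprints.append(iv)
    read_set = IntervalSet.from_intervals(targets.assembly, footprints).merge()
    per_interval = []
    for target in targets.merge():
        covered = sum(
            min(target.end, hit.end) - max(target.start, hit.start)
            for hit in read_set.search_overlapping(target)
        )
        per_interval.append(IntervalCoverage(target, covered))
    return CoverageSummary(tuple(per_interval))


@dataclass(frozen=True)
class TiTvSummary:
    """Transition/transversion counts for one stratum."""

    stratum: str
    transitions: int
    transversions: int

    @property
    def ratio(self) -> float | None:
        """Ti/Tv, or None (undefined) when there are no transversions."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def titv_summary(
    variants: Iterable[VcfRecord],
    strata: Mapping[str, IntervalSet],
) -> list[TiTvSummary]:
    """Per-stratum Ti/Tv counts.

    Each (REF, ALT) single-nucleotide pair counts once in every stratum
    whose region set overlaps the variant interval; non-SNV pairs are
    ignored.  Records whose REF is symbolic have no interval and are
    skipped.  Output order follows the strata mapping.
    """
    counts = {label: [0, 0] for label in strata}
    for rec in variants:
        classes = [classify_snv(rec.ref, alt) for alt in rec.alt]
        classes = [c for c in classes if c != NOT_SNV]
        if not classes:
            continue
        try:
            iv = vcf_to_interval(rec)
        except SymbolicAlleleError:
            continue
        for label, regions in strata.items():
            if iv.seq_name not in regions.assembly:
                continue
            if iv.end > regions.assembly.length_of(iv.seq_name):
                continue
            if regions.search_overlapping(iv):
                for cls in classes:
                    counts[label][0 if cls == TRANSITION else 1] += 1
    return [
        TiTvSummary(label, ti, tv) for label, (ti, tv) in counts.items()
    ]


def titv_table(summaries: Iterable[TiTvSummary]) -> str:
    lines = ["#stratum\ttransitions\ttransversions\tti_tv"]
    for s in summaries:
        ratio = "NA" if s.ratio is None else f"{s.ratio:.6g}"
        lines.append(f"{s.stratum}\t{s.transitions}\t{s.transversions}\t{ratio}")
    return "\n".join(lines) + "\n"
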