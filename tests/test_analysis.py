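"""Coverage breadth and Ti/Tv stratification."""

import pytest

from genomictk.analysis import coverage, titv_summary, titv_table
from genomictk.genome import GenomeAssembly, GenomicInterval
from genomictk.rbtree import IntervalSet
from genomictk.sam import parse_sam_record
from genomictk.synthetic import (
    GeneratorConfig,
    gen_assembly,
    gen_intervals,
    gen_records,
    gen_sam_header,
)
from genomictk.vcf import VcfHeader, parse_vcf_record

ASM = GenomeAssembly.from_pairs([("chr1", 10_000)])
HEADER = VcfHeader(("##fileformat=VCFv4.2",))


def _read(pos: int, cigar_len: int, flag: int = 0) -> object:
    seq = "A" * cigar_len
    return parse_sam_record(
        f"r\t{flag}\tchr1\t{pos}\t60\t{cigar_len}M\t*\t0\t0\t{seq}\t*"
    )


def _variant(pos: int, ref: str, alt: str):
    return parse_vcf_record(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.", HEADER)


class TestCoverage:
    def test_worked_toy(self):
        """Target 0..20 with reads covering 0..10 and 5..15: 15/20 covered."""
        targets = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 20)])
        reads = [_read(1, 10), _read(6, 10)]
        summary = coverage(targets, reads)
        (c,) = summary.per_interval
        assert c.covered == 15 and c.length == 20
        assert c.breadth == pytest.approx(0.75)

    def test_no_reads_gives_zero(self):
        targets = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 20)])
        summary = coverage(targets, [])
        assert summary.per_interval[0].covered == 0

    def test_exact_read_gives_breadth_one(self):
        targets = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 100, 150)])
        summary = coverage(targets, [_read(101, 50)])
        assert summary.per_interval[0].breadth == 1.0

    def test_secondary_and_supplementary_excluded_by_default(self):
        targets = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 20)])
        reads = [_read(1, 10, flag=0x100), _read(1, 10, flag=0x800)]
        assert coverage(targets, reads).per_interval[0].covered == 0
        assert (
            coverage(
                targets, reads, include_secondary=True,
                include_supplementary=True,
            ).per_interval[0].covered
            == 10
        )

    def test_matches_per_base_oracle_and_is_monotone(self):
        cfg = GeneratorConfig(seed=17, n_sequences=2,
                              seq_length_range=(2000, 8000))
        asm = gen_assembly(cfg)
        header_asm = gen_sam_header(asm).to_assembly()
        targets = IntervalSet.from_intervals(asm, gen_intervals(cfg, asm, 20))
        records, _ = gen_records(cfg, asm, "sam", 100)
        assert header_asm == asm
        prev = None
        for n_reads in (0, 25, 50, 100):
            summary = coverage(targets, records[:n_reads])
            # per-base oracle on this instance
            from genomictk.sam import sam_to_interval
            from genomictk.synthetic import oracle_interval_ops

            footprints = [
                iv
                for rec in records[:n_reads]
                if not rec.flag & 0x900
                for iv in [sam_to_interval(rec)]
                if iv is not None
            ]
            base = {
                name: bytearray(length) for name, length in asm
            }
            for iv in footprints:
                for i in range(iv.start, iv.end):
                    base[iv.seq_name][i] = 1
            for c in summary.per_interval:
                iv = c.interval
                expected = sum(base[iv.seq_name][iv.start : iv.end])
                assert c.covered == expected
                assert 0 <= c.breadth <= 1
            if prev is not None:
                assert all(
                    cur.covered >= old.covered
                    for cur, old in zip(summary.per_interval, prev)
                )  # monotone under read addition
            prev = summary.per_interval


class TestTiTv:
    def test_worked_toy_ratio_two(self):
        """{A>G, C>T, G>A, T>C, A>C, G>T} -> 4 Ti, 2 Tv, ratio 2.0."""
        subs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                ("A", "C"), ("G", "T")]
        variants = [
            _variant(10 * i + 1, r, a) for i, (r, a) in enumerate(subs)
        ]
        regions = IntervalSet.from_intervals(
            ASM, [GenomicInterval("chr1", 0, 10_000)]
        )
        (s,) = titv_summary(variants, {"all": regions})
        assert (s.transitions, s.transversions) == (4, 2)
        assert s.ratio == pytest.approx(2.0)

    def test_variant_outside_all_regions_ignored(self):
        regions = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 50)])
        (s,) = titv_summary([_variant(100, "A", "G")], {"r": regions})
        assert (s.transitions, s.transversions) == (0, 0)

    def test_zero_transversions_gives_undefined_ratio(self):
        regions = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 10_000)])
        (s,) = titv_summary([_variant(5, "A", "G")], {"r": regions})
        assert s.ratio is None
        assert "NA" in titv_table([s])

    def test_multiallelic_counts_once_per_alt(self):
        regions = IntervalSet.from_intervals(ASM, [GenomicInterval("chr1", 0, 10_000)])
        (s,) = titv_summary([_variant(5, "A", "G,C")], {"r": regions})
        assert (s.transitions, s.transversions) == (1, 1)

    def test_counts_invariant_under_permutation_and_additive_over_strata(self):
        cfg = GeneratorConfig(seed=23)
        asm = gen_assembly(cfg)
        records, _ = gen_records(cfg, asm, "vcf", 120)
        full = IntervalSet.from_intervals(
            asm, [GenomicInterval(n, 0, length) for n, length in asm]
        )
        half = IntervalSet.from_intervals(
            asm, [GenomicInterval(n, 0, length // 2) for n, length in asm]
        )
        rest = full.subtract(half)
        (fwd,) = titv_summary(records, {"all": full})
        (rev,) = titv_summary(list(reversed(records)), {"all": full})
        assert (fwd.transitions, fwd.transversions) == (
            rev.transitions,
            rev.transversions,
        )
        lo, hi = titv_summary(records, {"lo": half, "hi": rest})
        # strata are disjoint and exhaustive up to boundary-straddling refs
        straddlers = sum(
            1
            for rec in records
            if any(
                iv.start < length // 2 <= iv.end - 1
                for n, length in asm
                if n == rec.chrom
                for iv in [
                    GenomicInterval(rec.chrom, rec.pos - 1,
                                    rec.pos - 1 + len(rec.ref))
                ]
            )
        )
        total_lo_hi = (
            lo.transitions + hi.transitions,
            lo.transversions + hi.transversions,
        )
        if straddlers == 0:
            assert total_lo_hi == (fwd.transitions, fwd.transversions)
        else:  # straddling variants may count in both strata
            assert total_lo_hi[0] >= fwd.transitions
            assert total_lo_hi[1] >= fwd.transversions
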