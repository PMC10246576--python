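"""Seeded synthetic-fixture generators and the brute-force interval oracle.

Everything randomized in the test suite flows through this module: one
explicit :class:`random.Random` per generator invocation, seeded from a
:class:`GeneratorConfig`, so the full fixture corpus regenerates
byte-identically from (config, seed).  Generators only emit structurally
valid artifacts — every generated record passes its own module's
validators — unless a negative-case helper is used, whose outputs parsers
must reject with a diagnostic.

The fixtures exercise the *structural* properties of the formats (column
grammar, coordinate conventions, attribute escaping, binary packing), not
biological realism: there is no mutation model, no read-error profile, and
sequence content is uniform over ACGT.

:func:`oracle_interval_ops` is the independent ground truth for the
interval algebra: it materializes an explicit boolean occupancy array per
sequence, applies the set operation per base, and extracts maximal runs.
It shares no code with the red-black tree engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .bed import BedRecord, write_bed_record
from .genome import GenomeAssembly, GenomicInterval
from .gff import Gff3Record, GtfRecord, write_gff3_record, write_gtf_record
from .sam import Cigar, SamHeader, SamRecord, SamTag, write_sam_record
from .seqio import FastaRecord, FastqRecord
from .vcf import VcfHeader, VcfRecord, write_vcf_record
from .wig import FIXED, VARIABLE, WigValue

_ORACLE_BASE_LIMIT = 10**6
FORMATS = ("bed", "gff3", "gtf", "wig", "vcf", "sam", "fasta", "fastq")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic corpus; defaults give small, varied fixtures."""

    seed: int
    n_sequences: int = 3
    seq_length_range: tuple[int, int] = (1_000, 10_000)
    n_records_range: tuple[int, int] = (5, 50)
    interval_length_range: tuple[int, int] = (1, 500)
    score_range: tuple[int, int] = (0, 1000)
    read_length_range: tuple[int, int] = (20, 120)
    alphabet: str = "ACGT"
    attribute_tags: tuple[str, ...] = ("ID", "Name", "Parent", "Note")

    def rng(self, salt: int = 0) -> random.Random:
        # string seeding is stable across processes (sha512-based)
        return random.Random(f"{self.seed}:{salt}")


def gen_assembly(cfg: GeneratorConfig) -> GenomeAssembly:
    """Deterministic assembly: names seq1..seqN, lengths in the config range."""
    rng = cfg.rng(1)
    lo, hi = cfg.seq_length_range
    return GenomeAssembly.from_pairs(
        (f"seq{i + 1}", rng.randint(lo, hi)) for i in range(cfg.n_sequences)
    )


def gen_interval(
    rng: random.Random, cfg: GeneratorConfig, asm: GenomeAssembly
) -> GenomicInterval:
    name, length = rng.choice(asm.sequences)
    max_len = min(cfg.interval_length_range[1], length)
    iv_len = rng.randint(min(cfg.interval_length_range[0], max_len), max_len)
    start = rng.randint(0, length - iv_len)
    return GenomicInterval(
        name, start, start + iv_len, rng.choice("+-..")
    )


def gen_intervals(
    cfg: GeneratorConfig, asm: GenomeAssembly, n: int | None = None
) -> list[GenomicInterval]:
    rng = cfg.rng(2)
    if n is None:
        n = rng.randint(*cfg.n_records_range)
    return [gen_interval(rng, cfg, asm) for _ in range(n)]


# -- per-format record generators ---------------------------------------


def _gen_word(rng: random.Random, min_len: int = 1, max_len: int = 10) -> str:
    chars = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_"
    return "".join(
        rng.choice(chars) for _ in range(rng.randint(min_len, max_len))
    )


def _gen_seq(rng: random.Random, cfg: GeneratorConfig, length: int) -> str:
    return "".join(rng.choice(cfg.alphabet) for _ in range(length))


def _gen_bed(rng, cfg, asm, n) -> list[BedRecord]:
    out = []
    for _ in range(n):
        iv = gen_interval(rng, cfg, asm)
        n_extra = rng.choice((0, 0, 1, 2, 3, 3, 9))
        extra: list[str] = []
        if n_extra >= 1:
            extra.append(_gen_word(rng))
        if n_extra >= 2:
            extra.append(str(rng.randint(*cfg.score_range)))
        if n_extra >= 3:
            extra.append(rng.choice("+-."))
        if n_extra >= 9:  # BED12 with consistent blocks
            length = iv.end - iv.start
            extra.append(str(iv.start))  # thickStart
            extra.append(str(iv.end))  # thickEnd
            extra.append("0,0,0")  # itemRgb
            n_blocks = rng.randint(1, min(3, length))
            starts = sorted(rng.sample(range(length), n_blocks))
            sizes = [
                max(
                    1,
                    min(
                        (starts[i + 1] if i + 1 < n_blocks else length)
                        - starts[i],
                        rng.randint(1, max(1, length // n_blocks)),
                    ),
                )
                for i in range(n_blocks)
            ]
            extra.append(str(n_blocks))
            extra.append(",".join(map(str, sizes)) + ",")
            extra.append(",".join(map(str, starts)) + ",")
        out.append(BedRecord(iv.seq_name, iv.start, iv.end, tuple(extra)))
    return out


def _gen_attr_value(rng: random.Random) -> str:
    value = _gen_word(rng, 1, 8)
    if rng.random() < 0.3:  # exercise the percent-encoding path
        pos = rng.randint(0, len(value))
        value = value[:pos] + rng.choice("\t%;=&,") + value[pos:]
    return value


def _gen_gff3(rng, cfg, asm, n) -> list[Gff3Record]:
    out = []
    for _ in range(n):
        iv = gen_interval(rng, cfg, asm)
        ftype = rng.choice(("gene", "mRNA", "exon", "CDS", "repeat_region"))
        attrs = tuple(
            (
                tag,
                tuple(
                    _gen_attr_value(rng)
                    for _ in range(rng.choice((1, 1, 1, 2)))
                ),
            )
            for tag in rng.sample(
                cfg.attribute_tags, rng.randint(0, len(cfg.attribute_tags))
            )
        )
        out.append(
            Gff3Record(
                seqid=iv.seq_name,
                source=rng.choice((".", "test", "annot")),
                type=ftype,
                start=iv.start + 1,
                end=iv.end,
                score=rng.choice((".", "0", "0.0", str(rng.randint(0, 100)))),
                strand=rng.choice("+-.?"),
                phase=rng.choice(("0", "1", "2")) if ftype == "CDS"
                else ".",
                attributes=attrs,
            )
        )
    return out


def _gen_gtf(rng, cfg, asm, n) -> list[GtfRecord]:
    out = []
    for _ in range(n):
        iv = gen_interval(rng, cfg, asm)
        attrs = [("gene_id", _gen_word(rng)), ("transcript_id", _gen_word(rng))]
        if rng.random() < 0.5:
            attrs.append(("exon_number", str(rng.randint(1, 20))))
        out.append(
            GtfRecord(
                seqid=iv.seq_name,
                source="test",
                type=rng.choice(("gene", "transcript", "exon", "CDS")),
                start=iv.start + 1,
                end=iv.end,
                score=rng.choice((".", str(rng.randint(0, 100)))),
                strand=rng.choice("+-"),
                phase=".",
                attributes=tuple(attrs),
            )
        )
    return out


def _gen_wig(rng, cfg, asm, n) -> list[WigValue]:
    out: list[WigValue] = []
    while len(out) < n:
        name, length = rng.choice(asm.sequences)
        run = min(rng.randint(1, 10), n - len(out))
        if rng.random() < 0.5:  # fixedStep section
            step = rng.randint(1, 20)
            span = rng.randint(1, step)
            max_start = length - span - step * run
            if max_start < 0:
                continue
            start = rng.randint(0, max_start)
            for k in range(run):
                out.append(
                    WigValue(
                        name,
                        start + k * step,
                        span,
                        f"{rng.uniform(-10, 10):.4g}",
                        FIXED,
                        step,
                    )
                )
        else:  # variableStep section
            span = rng.randint(1, 5)
            positions = sorted(
                rng.sample(range(0, length - span), min(run, length - span))
            )
            for pos in positions:
                out.append(
                    WigValue(
                        name, pos, span, f"{rng.uniform(-10, 10):.4g}",
                        VARIABLE,
                    )
                )
    return out


def gen_vcf_header(rng: random.Random, asm: GenomeAssembly,
                   n_samples: int) -> VcfHeader:
    meta = ["##fileformat=VCFv4.2"]
    meta.append(
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">'
    )
    meta.append(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">'
    )
    meta.append('##INFO=<ID=DB,Number=0,Type=Flag,Description="In dbSNP">')
    meta.append('##FILTER=<ID=q10,Description="Quality below 10">')
    if n_samples:
        meta.append(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
    for name, length in asm:
        meta.append(f"##contig=<ID={name},length={length}>")
    samples = tuple(f"sample{i + 1}" for i in range(n_samples))
    return VcfHeader(tuple(meta), samples)


def _gen_vcf_record(rng, cfg, asm, n_samples: int) -> VcfRecord:
    name, length = rng.choice(asm.sequences)
    ref_len = rng.choice((1, 1, 1, 1, 2, 3))
    pos = rng.randint(1, length - ref_len)
    ref = _gen_seq(rng, cfg, ref_len)
    alts = []
    for _ in range(rng.choice((1, 1, 1, 2))):
        if rng.random() < 0.7:  # substitution of equal length
            alt = _gen_seq(rng, cfg, ref_len)
            while alt == ref:
                alt = _gen_seq(rng, cfg, ref_len)
        else:  # insertion relative to ref
            alt = ref + _gen_seq(rng, cfg, rng.randint(1, 4))
        alts.append(alt)
    info: list[tuple[str, str | None]] = [("DP", str(rng.randint(1, 500)))]
    if rng.random() < 0.5:
        info.append(
            ("AF", ",".join(f"{rng.uniform(0, 1):.3f}" for _ in alts))
        )
    if rng.random() < 0.3:
        info.append(("DB", None))
    fmt = ("GT",) if n_samples else None
    genotypes = tuple(
        "/".join(str(rng.randint(0, len(alts))) for _ in range(2))
        for _ in range(n_samples)
    )
    return VcfRecord(
        chrom=name,
        pos=pos,
        id=rng.choice((".", f"rs{rng.randint(1, 10**6)}")),
        ref=ref,
        alt=tuple(alts),
        qual=rng.choice((".", str(rng.randint(0, 99)), "50.0")),
        filter=rng.choice(("PASS", ".", "q10")),
        info=tuple(info),
        format_keys=fmt,
        sample_values=genotypes,
    )


def gen_cigar(rng: random.Random, query_length: int) -> Cigar:
    """A valid CIGAR consuming exactly *query_length* query bases."""
    lead = trail = 0
    if query_length > 5 and rng.random() < 0.3:
        lead = rng.randint(1, query_length // 3)
    if query_length > 5 and rng.random() < 0.3:
        trail = rng.randint(1, query_length // 3)
    mid = query_length - lead - trail
    if mid < 1:
        lead = trail = 0
        mid = query_length
    body: list[tuple[int, str]] = []
    remaining = mid
    prev_match = False
    while remaining > 0:
        if prev_match and rng.random() < 0.3:
            if rng.random() < 0.5:
                body.append((rng.randint(1, 10), "D"))
            else:
                take = rng.randint(1, remaining)
                body.append((take, "I"))
                remaining -= take
            prev_match = False
            continue
        take = rng.randint(1, remaining)
        body.append((take, rng.choice("MM=X")))
        remaining -= take
        prev_match = True
    while body and body[-1][1] in "ID":  # end the alignment on a match-type op
        length, op = body.pop()
        if op == "I":
            body.append((length, "M"))  # same query consumption
    ops: list[tuple[int, str]] = []
    if lead:
        ops.append((lead, "S"))
    ops.extend(body)
    if trail:
        ops.append((trail, "S"))
    return Cigar(tuple(ops))


def gen_sam_header(asm: GenomeAssembly) -> SamHeader:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in asm:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append("@PG\tID:synth\tPN:genomictk-synth")
    return SamHeader.parse(lines)


def _gen_sam_record(rng, cfg, asm) -> SamRecord:
    qname = f"read{rng.randint(1, 10**6)}"
    read_len = rng.randint(*cfg.read_length_range)
    seq = _gen_seq(rng, cfg, read_len)
    qual = "".join(chr(rng.randint(33, 73)) for _ in range(read_len))
    tags = [SamTag("NM", "i", rng.randint(0, 20))]
    if rng.random() < 0.5:
        tags.append(SamTag("AS", "i", rng.randint(-100, 200)))
    if rng.random() < 0.3:
        tags.append(SamTag("XF", "f", rng.randint(-400, 400) / 4))
    if rng.random() < 0.3:
        tags.append(SamTag("RG", "Z", _gen_word(rng)))
    if rng.random() < 0.2:
        tags.append(
            SamTag(
                "XB",
                "B",
                ("i", tuple(rng.randint(-100, 100) for _ in range(3))),
            )
        )
    if rng.random() < 0.1:  # unmapped read
        return SamRecord(
            qname=qname,
            flag=0x4,
            rname=None,
            pos=0,
            mapq=0,
            cigar=None,
            rnext=None,
            pnext=0,
            tlen=0,
            seq=seq,
            qual=qual,
            tags=tuple(tags),
        )
    cigar = gen_cigar(rng, read_len)
    name, length = rng.choice(asm.sequences)
    span = cigar.reference_span()
    if span >= length:
        cigar = Cigar(((read_len, "M"),))
        span = read_len
    pos = rng.randint(1, length - span)
    flag = rng.choice((0, 16, 0, 16, 256, 2048))
    return SamRecord(
        qname=qname,
        flag=flag,
        rname=name,
        pos=pos,
        mapq=rng.randint(0, 60),
        cigar=cigar,
        rnext=None,
        pnext=0,
        tlen=0,
        seq=seq,
        qual=qual,
        tags=tuple(tags),
    )


def _gen_fasta(rng, cfg, asm, n) -> list[FastaRecord]:
    return [
        FastaRecord(
            identifier=_gen_word(rng),
            description=_gen_word(rng, 0, 20) if rng.random() < 0.5 else "",
            sequence=_gen_seq(rng, cfg, rng.randint(0, 200)),
        )
        for _ in range(n)
    ]


def _gen_fastq(rng, cfg, asm, n) -> list[FastqRecord]:
    out = []
    for _ in range(n):
        length = rng.randint(1, 150)
        out.append(
            FastqRecord(
                identifier=_gen_word(rng),
                description=_gen_word(rng, 0, 12)
                if rng.random() < 0.3
                else "",
                sequence=_gen_seq(rng, cfg, length),
                quality="".join(
                    chr(rng.randint(33, 73)) for _ in range(length)
                ),
            )
        )
    return out


def gen_records(
    cfg: GeneratorConfig,
    asm: GenomeAssembly,
    fmt: str,
    n: int | None = None,
) -> tuple[list, str]:
    """Generate *n* valid records of *fmt* plus the serialized file image.

    The image parses back to records equal to the returned ones — the seed
    property of every round-trip suite.
    """
    rng = cfg.rng(10 + FORMATS.index(fmt))
    if n is None:
        n = rng.randint(*cfg.n_records_range)
    if fmt == "bed":
        records = _gen_bed(rng, cfg, asm, n)
        image = "".join(write_bed_record(r) + "\n" for r in records)
    elif fmt == "gff3":
        records = _gen_gff3(rng, cfg, asm, n)
        image = "##gff-version 3\n" + "".join(
            write_gff3_record(r) + "\n" for r in records
        )
    elif fmt == "gtf":
        records = _gen_gtf(rng, cfg, asm, n)
        image = "".join(write_gtf_record(r) + "\n" for r in records)
    elif fmt == "wig":
        from io import StringIO

        from .wig import write_wig

        records = _gen_wig(rng, cfg, asm, n)
        buf = StringIO()
        write_wig(records, buf)
        image = buf.getvalue()
    elif fmt == "vcf":
        n_samples = rng.choice((0, 0, 1, 2))
        header = gen_vcf_header(rng, asm, n_samples)
        records = [_gen_vcf_record(rng, cfg, asm, n_samples) for _ in range(n)]
        image = (
            "\n".join(header.meta_lines)
            + "\n"
            + header.column_line()
            + "\n"
            + "".join(write_vcf_record(r) + "\n" for r in records)
        )
    elif fmt == "sam":
        header = gen_sam_header(asm)
        records = [_gen_sam_record(rng, cfg, asm) for _ in range(n)]
        image = header.to_text() + "".join(
            write_sam_record(r) + "\n" for r in records
        )
    elif fmt == "fasta":
        from io import StringIO

        from .seqio import write_fasta

        records = _gen_fasta(rng, cfg, asm, n)
        buf = StringIO()
        write_fasta(records, buf)
        image = buf.getvalue()
    elif fmt == "fastq":
        from io import StringIO

        from .seqio import write_fastq

        records = _gen_fastq(rng, cfg, asm, n)
        buf = StringIO()
        write_fastq(records, buf)
        image = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return records, image


def corrupt_line(rng: random.Random, fmt: str, line: str) -> str:
    """Break one data line so its parser must reject it with a diagnostic."""
    if fmt == "bed":
        fields = line.split("\t")
        return "\t".join([fields[0], fields[2], fields[1], *fields[3:]])
    if fmt in ("gff3", "gtf"):
        return "\t".join(line.split("\t")[:8])  # drop the attribute column
    if fmt == "vcf":
        fields = line.split("\t")
        fields[1] = "notanumber"
        return "\t".join(fields)
    if fmt == "sam":
        return "\t".join(line.split("\t")[:7])  # too few mandatory fields
    if fmt == "fastq":
        return line[1:] if line.startswith("@") else "@" + line
    return line + "\t\x00"


# -- per-base occupancy oracle ------------------------------------------


def _occupancy(
    asm: GenomeAssembly, intervals: list[GenomicInterval]
) -> dict[str, bytearray]:
    arrays = {name: bytearray(length) for name, length in asm}
    for iv in intervals:
        arr = arrays[iv.seq_name]
        for i in range(iv.start, iv.end):
            arr[i] = 1
    return arrays


def _runs(asm: GenomeAssembly, arrays: dict[str, bytearray]) -> list[GenomicInterval]:
    out = []
    for name in asm.names:
        arr = arrays[name]
        start = None
        for i, v in enumerate(arr):
            if v and start is None:
                start = i
            elif not v and start is not None:
                out.append(GenomicInterval(name, start, i))
                start = None
        if start is not None:
            out.append(GenomicInterval(name, start, len(arr)))
    return out


def oracle_interval_ops(
    asm: GenomeAssembly,
    intervals: list[GenomicInterval],
    op: str,
    other: list[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Ground-truth merge/intersect/subtract/complement via per-base arrays.

    Only usable when the assembly totals at most 10^6 bases.
    """
    total = sum(length for _, length in asm)
    if total > _ORACLE_BASE_LIMIT:
        raise ValueError(
            f"assembly has {total} bases; the oracle is limited to "
            f"{_ORACLE_BASE_LIMIT}"
        )
    a = _occupancy(asm, intervals)
    if op == "merge":
        return _runs(asm, a)
    if op == "complement":
        for arr in a.values():
            for i in range(len(arr)):
                arr[i] ^= 1
        return _runs(asm, a)
    if other is None:
        raise ValueError(f"operation {op!r} needs a second interval list")
    b = _occupancy(asm, other)
    for name in a:
        arr_a, arr_b = a[name], b[name]
        if op == "intersect":
            for i in range(len(arr_a)):
                arr_a[i] &= arr_b[i]
        elif op == "subtract":
            for i in range(len(arr_a)):
                arr_a[i] &= arr_b[i] ^ 1
        else:
            raise ValueError(f"unknown operation {op!r}")
    return _runs(asm, a)
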