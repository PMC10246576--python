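"""Randomized validation campaigns over the whole toolkit.

Each function here runs one seeded campaign — oracle equivalence of the
interval algebra, the red-black structural audit, persistence checks,
round-trip suites for every text format, and the BAM/BGZF binary checks —
and returns measured counts rather than raising, so callers (the test
suite, the acceptance script, or an interactive session) can report them.
A campaign is deterministic in its seed.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass

from .bam import read_bam, write_bam
from .bed import BedRecord, read_bed, write_bed_record
from .bgzf import EOF_BLOCK, bgzf_compress, bgzf_decompress, split_blocks
from .genome import GenomicInterval
from .gff import read_gff3, read_gtf, write_gff3_record, write_gtf_record
from .rbtree import IntervalSet, audit_tree
from .sam import read_sam, write_sam_record
from .seqio import read_fasta, read_fastq, write_fasta, write_fastq
from .synthetic import (
    FORMATS,
    GeneratorConfig,
    gen_assembly,
    gen_intervals,
    gen_records,
    oracle_interval_ops,
)
from .vcf import read_vcf_stream, write_vcf_record
from .wig import read_wig, write_wig


def _spans(items) -> list[tuple[str, int, int]]:
    return [(iv.seq_name, iv.start, iv.end) for iv in items]


def run_oracle_equivalence(seed: int, n_instances: int = 1000) -> dict:
    """Compare merge/intersect/subtract/complement against the per-base
    coverage-array oracle on random instances (<= 100 intervals each,
    sequences <= 10^4 bp).  Returns operation-level mismatch counts."""
    mismatches = {op: 0 for op in ("merge", "intersect", "subtract", "complement")}
    for k in range(n_instances):
        cfg = GeneratorConfig(
            seed=seed * 1_000_003 + k,
            n_sequences=2,
            seq_length_range=(500, 10_000),
            interval_length_range=(1, 600),
        )
        asm = gen_assembly(cfg)
        rng = cfg.rng(3)
        a_ivs = gen_intervals(cfg, asm, rng.randint(0, 100))
        b_cfg = GeneratorConfig(seed=seed * 1_000_003 + k + 500_000_009)
        b_ivs = gen_intervals(b_cfg, asm, rng.randint(0, 100))
        a = IntervalSet.from_intervals(asm, a_ivs)
        b = IntervalSet.from_intervals(asm, b_ivs)
        results = {
            "merge": a.merge(),
            "intersect": a.intersect(b),
            "subtract": a.subtract(b),
            "complement": a.complement(),
        }
        for op, result in results.items():
            expected = oracle_interval_ops(asm, a_ivs, op, b_ivs)
            if _spans(result) != _spans(expected):
                mismatches[op] += 1
    return {
        "instances": n_instances,
        "mismatches": mismatches,
        "total_mismatches": sum(mismatches.values()),
    }


def run_structure_audit(seed: int, n_inserts: int = 10_000) -> dict:
    """Insert *n_inserts* random intervals and audit every red-black and
    augmentation invariant plus the 2*log2(n+1) height bound."""
    cfg = GeneratorConfig(
        seed=seed, n_sequences=1, seq_length_range=(10**6, 10**6),
        interval_length_range=(1, 10_000),
    )
    asm = gen_assembly(cfg)
    rng = cfg.rng(7)
    s = IntervalSet(asm)
    for _ in range(n_inserts):
        start = rng.randint(0, 10**6 - 10_001)
        s = s.insert(GenomicInterval("seq1", start, start + rng.randint(1, 10_000)))
    violations = 0
    height = 0
    try:
        _, count, height = audit_tree(s.root("seq1"))
        assert count == n_inserts
        bound = 2 * math.log2(n_inserts + 1)
        if height > bound:
            violations += 1
    except AssertionError:
        violations += 1
    return {"inserts": n_inserts, "violations": violations, "height": height}


def run_persistence_trials(seed: int, n_trials: int = 100) -> dict:
    """Randomized operation sequences; count any trial where a pre-operation
    snapshot differs from the set afterwards."""
    failures = 0
    for k in range(n_trials):
        cfg = GeneratorConfig(seed=seed * 7_919 + k, n_sequences=2,
                              seq_length_range=(1_000, 5_000))
        asm = gen_assembly(cfg)
        rng = cfg.rng(9)
        a = IntervalSet.from_intervals(asm, gen_intervals(cfg, asm, rng.randint(1, 50)))
        b = IntervalSet.from_intervals(
            asm,
            gen_intervals(GeneratorConfig(seed=seed * 7_919 + k + 1), asm,
                          rng.randint(1, 50)),
        )
        snap_a, snap_b = a.to_list(), b.to_list()
        for _ in range(rng.randint(1, 8)):
            op = rng.choice(("merge", "intersect", "subtract", "complement",
                             "insert", "search"))
            if op == "merge":
                a.merge()
            elif op == "intersect":
                a.intersect(b)
            elif op == "subtract":
                a.subtract(b)
            elif op == "complement":
                a.complement()
            elif op == "insert":
                name, length = rng.choice(asm.sequences)
                start = rng.randint(0, length - 2)
                a.insert(GenomicInterval(name, start, start + 1))
            else:
                name, length = rng.choice(asm.sequences)
                a.search_overlapping(GenomicInterval(name, 0, length))
        if a.to_list() != snap_a or b.to_list() != snap_b:
            failures += 1
    return {"trials": n_trials, "failures": failures}


def run_roundtrip_suite(seed: int, per_format: int = 500) -> dict:
    """write(parse(x)) == x and parse(write(r)) == r for every format.

    Byte-exact except the two documented lossy directions (FASTA
    re-wrapping, which the generator sidesteps by writing unwrapped, and
    SAM integer-tag width canonicalization, which the text generator never
    produces).  Returns per-format failure counts.
    """
    failures: dict[str, int] = {}
    cfg = GeneratorConfig(seed=seed)
    asm = gen_assembly(cfg)
    for fmt in FORMATS:
        records, image = gen_records(cfg, asm, fmt, per_format)
        bad = 0
        if fmt == "bed":
            parsed = [r for r in read_bed(io.StringIO(image))
                      if isinstance(r, BedRecord)]
            rebuilt = "".join(write_bed_record(r) + "\n" for r in parsed)
        elif fmt == "gff3":
            parsed = [r for r in read_gff3(io.StringIO(image))
                      if not isinstance(r, str)]
            rebuilt = "##gff-version 3\n" + "".join(
                write_gff3_record(r) + "\n" for r in parsed
            )
        elif fmt == "gtf":
            parsed = [r for r in read_gtf(io.StringIO(image))
                      if not isinstance(r, str)]
            rebuilt = "".join(write_gtf_record(r) + "\n" for r in parsed)
        elif fmt == "wig":
            parsed = read_wig(io.StringIO(image))
            buf = io.StringIO()
            write_wig(parsed, buf)
            rebuilt = buf.getvalue()
        elif fmt == "vcf":
            header, it = read_vcf_stream(io.StringIO(image))
            parsed = list(it)
            rebuilt = (
                "\n".join(header.meta_lines) + "\n" + header.column_line()
                + "\n" + "".join(write_vcf_record(r) + "\n" for r in parsed)
            )
        elif fmt == "sam":
            header, it = read_sam(io.StringIO(image))
            parsed = list(it)
            rebuilt = header.to_text() + "".join(
                write_sam_record(r) + "\n" for r in parsed
            )
        elif fmt == "fasta":
            parsed = list(read_fasta(io.StringIO(image)))
            buf = io.StringIO()
            write_fasta(parsed, buf)
            rebuilt = buf.getvalue()
        else:
            parsed = list(read_fastq(io.StringIO(image)))
            buf = io.StringIO()
            write_fastq(parsed, buf)
            rebuilt = buf.getvalue()
        if list(parsed) != list(records):
            bad += 1
        if rebuilt != image:
            bad += 1
        failures[fmt] = bad
    return {"per_format": per_format, "failures": failures,
            "total_failures": sum(failures.values())}


def run_bam_bgzf_suite(
    seed: int,
    n_files: int = 100,
    n_payloads: int = 100,
    max_payload: int = 1 << 20,
    records_per_file: int = 25,
) -> dict:
    """BAM write/read identity, BGZF round-trips against the generic gzip
    oracle, the 28-byte empty stream, and CRC/ISIZE revalidation."""
    bam_failures = 0
    for k in range(n_files):
        cfg = GeneratorConfig(seed=seed * 31 + k)
        asm = gen_assembly(cfg)
        _, image = gen_records(cfg, asm, "sam", records_per_file)
        header, it = read_sam(io.StringIO(image))
        records = list(it)
        h2, it2 = read_bam(write_bam(header, records))
        if h2 != header or list(it2) != records:
            bam_failures += 1
    rng = GeneratorConfig(seed=seed).rng(13)
    bgzf_failures = 0
    crc_failures = 0
    for _ in range(n_payloads):
        payload = rng.randbytes(rng.randint(0, max_payload))
        stream = bgzf_compress(payload)
        back, _ = bgzf_decompress(stream)
        if back != payload or gzip.decompress(stream) != payload:
            bgzf_failures += 1
        for block in split_blocks(stream):
            import zlib

            data = zlib.decompress(block.payload, wbits=-15)
            if len(data) != block.isize or zlib.crc32(data) != block.crc32:
                crc_failures += 1
    empty = bgzf_compress(b"")
    return {
        "bam_files": n_files,
        "bam_failures": bam_failures,
        "bgzf_payloads": n_payloads,
        "bgzf_failures": bgzf_failures,
        "crc_failures": crc_failures,
        "empty_stream_bytes": len(empty),
        "empty_is_eof_block": empty == EOF_BLOCK,
        "empty_gzip_decompresses_empty": gzip.decompress(empty) == b"",
    }
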