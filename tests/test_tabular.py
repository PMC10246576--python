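"""BED, GFF3, GTF and WIG: parsing, coordinate conventions, round-trips."""

import io

import pytest

from genomictk.bed import BedRecord, bed_to_interval, parse_bed_line, read_bed, write_bed_record
from genomictk.errors import FormatError
from genomictk.gff import (
    feature_to_interval,
    parse_gff3_record,
    parse_gtf_record,
    read_gff3,
    read_gtf,
    write_gff3_record,
    write_gtf_record,
)
from genomictk.synthetic import gen_records
from genomictk.wig import WigValue, read_wig, wig_to_interval, write_wig


class TestBed:
    def test_bed3(self):
        rec = parse_bed_line("chr1\t10\t20")
        assert (rec.chrom, rec.chrom_start, rec.chrom_end) == ("chr1", 10, 20)
        assert rec.name is None and rec.score is None and rec.strand is None

    def test_bed6(self):
        rec = parse_bed_line("chr1\t10\t20\tfeat1\t0\t+")
        assert rec.name == "feat1" and rec.score == 0 and rec.strand == "+"

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t20\t10",  # start >= end
            "chr1\t10",  # too few columns
            "chr1\tx\t20",  # non-numeric start
            "chr1\t10\t20\tn\t2000\t+",  # score out of range
            "chr1\t10\t20\tn\t0\t+\t10\t20\t0\t2\t1,\t0,",  # block count mismatch
        ],
    )
    def test_malformed_lines_rejected(self, line):
        with pytest.raises(FormatError):
            parse_bed_line(line)

    def test_to_interval_passthrough(self):
        iv = bed_to_interval(parse_bed_line("chr1\t10\t20\tx\t5\t-"))
        assert (iv.seq_name, iv.start, iv.end, iv.strand) == ("chr1", 10, 20, "-")

    def test_track_and_comment_lines_preserved(self):
        text = "track name=test\n# comment\nchr1\t0\t5\n"
        items = list(read_bed(io.StringIO(text)))
        assert items[0] == "track name=test"
        assert items[1] == "# comment"
        assert isinstance(items[2], BedRecord)


class TestGff3:
    def test_basic_parse_and_interval(self):
        rec = parse_gff3_record("chr1\t.\tgene\t11\t20\t.\t+\t.\tID=g1")
        assert rec.start == 11 and rec.end == 20
        assert rec.attributes == (("ID", ("g1",)),)
        iv = feature_to_interval(rec)
        assert (iv.start, iv.end) == (10, 20)  # 1-based inclusive -> 0-based

    def test_single_base_feature(self):
        rec = parse_gff3_record("c\t.\tSNP\t1\t1\t.\t.\t.\tID=v1")
        iv = feature_to_interval(rec)
        assert (iv.start, iv.end) == (0, 1)

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t.\tgene\t11\t20\t.\t+\t.",  # 8 columns
            "chr1\t.\tgene\t20\t11\t.\t+\t.\tID=g1",  # start > end
            "chr1\t.\tgene\t11\t20\t.\t+\t.\tnoequals",  # attr syntax
        ],
    )
    def test_malformed_rejected(self, line):
        with pytest.raises(FormatError):
            parse_gff3_record(line)

    def test_percent_coding_bijection(self):
        line = "chr1\t.\tgene\t1\t5\t.\t+\t.\tNote=a%3Bb%2Cc,second%3Dpart"
        rec = parse_gff3_record(line)
        assert rec.attribute("Note") == ("a;b,c", "second=part")
        assert write_gff3_record(rec) == line

    def test_directives_pass_through(self):
        text = "##gff-version 3\nchr1\t.\tgene\t1\t5\t.\t+\t.\tID=g\n"
        items = list(read_gff3(io.StringIO(text)))
        assert items[0] == "##gff-version 3"


class TestGtf:
    def test_attribute_order_preserved(self):
        rec = parse_gtf_record(
            'chr1\tt\texon\t1\t10\t.\t+\t.\tgene_id "g1"; transcript_id "t1";'
        )
        assert rec.attributes == (("gene_id", "g1"), ("transcript_id", "t1"))

    def test_missing_trailing_semicolon_rejected(self):
        with pytest.raises(FormatError):
            parse_gtf_record('chr1\tt\texon\t1\t10\t.\t+\t.\tgene_id "g1"')

    def test_write_is_inverse(self):
        line = 'chr1\tt\tCDS\t5\t30\t0.5\t-\t.\tgene_id "g"; exon_number "2";'
        assert write_gtf_record(parse_gtf_record(line)) == line


class TestWig:
    def test_fixed_step_expansion(self):
        text = "fixedStep chrom=chr1 start=1 step=10 span=5\n1.0\n2.0\n"
        values = read_wig(io.StringIO(text))
        assert [(v.chrom, v.start, v.span, v.value) for v in values] == [
            ("chr1", 0, 5, "1.0"),
            ("chr1", 10, 5, "2.0"),
        ]

    def test_variable_step_is_one_based(self):
        values = read_wig(io.StringIO("variableStep chrom=chr1\n11 3.5\n"))
        assert len(values) == 1
        v = values[0]
        assert (v.chrom, v.start, v.span, v.value) == ("chr1", 10, 1, "3.5")

    def test_value_before_declaration_rejected(self):
        with pytest.raises(FormatError):
            read_wig(io.StringIO("1.0\n"))

    def test_to_interval(self):
        v = WigValue("chr1", 10, 5, "1.5")
        iv = wig_to_interval(v)
        assert (iv.start, iv.end) == (10, 15)

    def test_span_step_consistency_errors(self):
        with pytest.raises(FormatError):
            read_wig(
                io.StringIO("fixedStep chrom=c start=1 step=2 span=5\n1\n")
            )


class TestRoundTrips:
    """write(parse(x)) == x and parse(write(r)) == r on the seeded corpus."""

    @pytest.mark.parametrize("fmt", ["bed", "gff3", "gtf", "wig"])
    def test_round_trip_on_generated_corpus(self, cfg, assembly, fmt):
        records, image = gen_records(cfg, assembly, fmt, 300)
        if fmt == "bed":
            parsed = [r for r in read_bed(io.StringIO(image)) if isinstance(r, BedRecord)]
            rebuilt = "".join(write_bed_record(r) + "\n" for r in parsed)
        elif fmt == "gff3":
            parsed = [r for r in read_gff3(io.StringIO(image)) if not isinstance(r, str)]
            rebuilt = "##gff-version 3\n" + "".join(
                write_gff3_record(r) + "\n" for r in parsed
            )
        elif fmt == "gtf":
            parsed = [r for r in read_gtf(io.StringIO(image)) if not isinstance(r, str)]
            rebuilt = "".join(write_gtf_record(r) + "\n" for r in parsed)
        else:
            parsed = read_wig(io.StringIO(image))
            buf = io.StringIO()
            write_wig(parsed, buf)
            rebuilt = buf.getvalue()
        assert parsed == records  # parse o write = identity on records
        assert rebuilt == image  # write o parse = identity on bytes
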