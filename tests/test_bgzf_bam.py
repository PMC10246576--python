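"""BGZF codec and BAM binary encoding, cross-checked against independent
implementations (the generic gzip codec and samtools)."""

import gzip
import io
import shutil
import subprocess
import zlib

import pytest

from genomictk.bam import read_bam, reg2bin, write_bam
from genomictk.bgzf import (
    EOF_BLOCK,
    VirtualOffset,
    bgzf_compress,
    bgzf_decompress,
    split_blocks,
)
from genomictk.errors import BgzfError, CrcMismatchError, FormatError
from genomictk.sam import read_sam, write_sam_record
from genomictk.synthetic import GeneratorConfig, gen_assembly, gen_records


class TestBgzf:
    def test_empty_payload_is_exactly_the_28_byte_eof_block(self):
        stream = bgzf_compress(b"")
        assert stream == EOF_BLOCK and len(stream) == 28
        assert gzip.decompress(stream) == b""  # generic gzip oracle

    def test_round_trip_identity(self):
        rng = GeneratorConfig(seed=2).rng(0)
        for size in (1, 100, 65280, 65281, 400_000):
            payload = rng.randbytes(size)
            back, index = bgzf_decompress(bgzf_compress(payload))
            assert back == payload
            assert index[0] == (0, 0)

    def test_generic_gzip_decompresses_our_stream(self):
        payload = GeneratorConfig(seed=3).rng(0).randbytes(200_000)
        assert gzip.decompress(bgzf_compress(payload)) == payload

    def test_block_crc_and_isize_revalidate(self):
        payload = GeneratorConfig(seed=4).rng(0).randbytes(150_000)
        for block in split_blocks(bgzf_compress(payload)):
            data = zlib.decompress(block.payload, wbits=-15)
            assert len(data) == block.isize <= 65536
            assert zlib.crc32(data) == block.crc32

    def test_generic_gzip_stream_rejected_as_non_bgzf(self):
        with pytest.raises(BgzfError):
            bgzf_decompress(gzip.compress(b"not bgzf"))

    def test_crc_corruption_detected(self):
        stream = bytearray(bgzf_compress(b"x" * 1000))
        blocks = split_blocks(bytes(stream))
        # flip a byte inside the first block's compressed payload
        first_payload_at = 18
        stream[first_payload_at] ^= 0xFF
        with pytest.raises((CrcMismatchError, BgzfError, zlib.error)):
            bgzf_decompress(bytes(stream))
        assert blocks  # sanity

    def test_missing_eof_block_warns(self):
        stream = bgzf_compress(b"abc")[: -len(EOF_BLOCK)]
        with pytest.warns(UserWarning):
            bgzf_decompress(stream)
        with pytest.raises(BgzfError):
            bgzf_decompress(stream, require_eof=True)


class TestVirtualOffset:
    def test_packing(self):
        vo = VirtualOffset(12345, 678)
        assert VirtualOffset.from_packed(vo.packed) == vo
        assert vo.packed == 12345 * 2**16 + 678

    def test_zero_resolves_to_zero(self):
        payload = b"hello world"
        _, index = bgzf_decompress(bgzf_compress(payload))
        assert VirtualOffset(0, 0).resolve(index) == 0

    def test_resolution_equals_full_decompression_slice(self):
        rng = GeneratorConfig(seed=6).rng(0)
        payload = rng.randbytes(200_000)
        stream = bgzf_compress(payload)
        back, index = bgzf_decompress(stream)
        for coffset, uoffset in index:
            for within in (0, 17, 1000):
                vo = VirtualOffset(coffset, within)
                absolute = vo.resolve(index)
                assert back[absolute : absolute + 50] == payload[
                    absolute : absolute + 50
                ]


class TestBam:
    def _generated(self, seed, n=60):
        cfg = GeneratorConfig(seed=seed)
        asm = gen_assembly(cfg)
        _, image = gen_records(cfg, asm, "sam", n)
        header, it = read_sam(io.StringIO(image))
        return header, list(it), image

    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_identity(self, seed):
        header, records, _ = self._generated(seed)
        h2, it2 = read_bam(write_bam(header, records))
        assert h2 == header
        assert list(it2) == records

    def test_empty_record_list(self):
        header, _, _ = self._generated(1, n=1)
        h2, it2 = read_bam(write_bam(header, []))
        assert h2 == header and list(it2) == []

    def test_bad_magic_rejected(self):
        from genomictk.bgzf import bgzf_compress as bc

        with pytest.raises(FormatError):
            read_bam(bc(b"BAI\x01" + b"\x00" * 8))

    def test_all_nine_cigar_ops_survive_encoding(self):
        from genomictk.sam import Cigar, SamHeader, SamRecord

        header = SamHeader.parse(["@SQ\tSN:c\tLN:10000"])
        cigar = Cigar(
            ((2, "H"), (3, "S"), (10, "M"), (2, "I"), (3, "D"), (5, "N"),
             (1, "P"), (4, "="), (2, "X"), (1, "S"), (1, "H"))
        )
        rec = SamRecord(
            qname="r", flag=0, rname="c", pos=50, mapq=60, cigar=cigar,
            rnext=None, pnext=0, tlen=0,
            seq="A" * cigar.query_length(), qual=None,
        )
        _, it = read_bam(write_bam(header, [rec]))
        (back,) = list(it)
        assert back.cigar == cigar

    def test_4bit_sequence_nibble_table(self):
        """Packed 0x18 decodes to 'AT' per the '=ACMGRSVTWYHKDBN' table."""
        from genomictk.bam import _decode_seq, _encode_seq

        assert _decode_seq(bytes([0x18]), 2) == "AT"
        assert _encode_seq("AT") == bytes([0x18])
        for i, base in enumerate("=ACMGRSVTWYHKDBN"):
            assert _encode_seq(base) == bytes([i << 4])

    def test_reg2bin_against_reference_values(self):
        # values computed from the piecewise definition by hand
        assert reg2bin(0, 1) == 4681
        assert reg2bin(0, 1 << 14) == 4681
        assert reg2bin(0, (1 << 14) + 1) == 585
        assert reg2bin(1 << 14, (1 << 14) + 1) == 4682

    @pytest.mark.skipif(
        shutil.which("samtools") is None, reason="samtools not on PATH"
    )
    def test_samtools_reads_our_bam_identically(self, tmp_path):
        header, records, image = self._generated(7)
        path = tmp_path / "ours.bam"
        path.write_bytes(write_bam(header, records))
        out = subprocess.run(
            ["samtools", "view", "-h", str(path)],
            capture_output=True,
            text=True,
            check=True,
        )
        ours = [ln for ln in image.splitlines() if not ln.startswith("@PG")]
        theirs = [
            ln for ln in out.stdout.splitlines() if not ln.startswith("@PG")
        ]
        assert ours == theirs

    @pytest.mark.skipif(
        shutil.which("samtools") is None, reason="samtools not on PATH"
    )
    def test_we_read_samtools_bam(self, tmp_path):
        header, records, image = self._generated(8)
        sam_path = tmp_path / "in.sam"
        sam_path.write_text(image)
        bam_path = tmp_path / "st.bam"
        subprocess.run(
            ["samtools", "view", "-b", "-o", str(bam_path), str(sam_path)],
            check=True,
        )
        _, it = read_bam(bam_path.read_bytes())
        rendered = [write_sam_record(r) for r in it]
        expected = [
            ln for ln in image.splitlines() if not ln.startswith("@")
        ]
        assert rendered == expected
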