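"""BGZF: blocked gzip, the container format BAM mandates.

A BGZF stream is a concatenation of independent gzip members, each at most
64 KiB of uncompressed payload, carrying the total block size (minus one)
in a ``BC`` extra subfield so a reader can jump from block to block without
inflating.  A *virtual offset* addresses a byte in the stream as
``compressed_block_offset << 16 | within_block_offset``.

The writer splits payloads into 65280-byte chunks (the conventional maximum
that leaves room for the 26 bytes of per-block overhead) and terminates the
stream with the canonical 28-byte empty block.  The reader validates the
gzip magic, the BC subfield, and by default the CRC32 and ISIZE of every
block; a generic gzip stream without the BC subfield is rejected with a
bad-magic error.
"""

from __future__ import annotations

import struct
import warnings
import zlib
from dataclasses import dataclass
from typing import IO

from .errors import BgzfError, CrcMismatchError

#: Maximum uncompressed bytes per block on write.
MAX_BLOCK_PAYLOAD = 65280

#: The canonical empty block every BGZF stream must end with.
EOF_BLOCK = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class BgzfBlock:
    """One compressed block plus the sizes a validator needs."""

    compressed_offset: int
    bsize: int  # total block size minus one (the BC subfield value)
    payload: bytes  # compressed (raw deflate) payload
    crc32: int
    isize: int  # uncompressed payload size

    def decompress(self, check_crc: bool = True) -> bytes:
        data = zlib.decompress(self.payload, wbits=-15)
        if len(data) != self.isize:
            raise BgzfError(
                f"block at {self.compressed_offset}: ISIZE {self.isize} != "
                f"actual {len(data)}"
            )
        if check_crc and zlib.crc32(data) != self.crc32:
            raise CrcMismatchError(
                f"block at {self.compressed_offset}: CRC mismatch"
            )
        return data


@dataclass(frozen=True)
class VirtualOffset:
    """64-bit BGZF address: (compressed block offset, within-block offset)."""

    block_offset: int
    within_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.within_offset < 1 << 16:
            raise ValueError("within-block offset must fit in 16 bits")
        if not 0 <= self.block_offset < 1 << 48:
            raise ValueError("block offset must fit in 48 bits")

    @property
    def packed(self) -> int:
        return (self.block_offset << 16) | self.within_offset

    @classmethod
    def from_packed(cls, value: int) -> "VirtualOffset":
        return cls(value >> 16, value & 0xFFFF)

    def resolve(self, block_index: list[tuple[int, int]]) -> int:
        """Absolute uncompressed position, given the decompression index of
        (compressed offset, uncompressed offset) pairs."""
        for coffset, uoffset in block_index:
            if coffset == self.block_offset:
                return uoffset + self.within_offset
        raise BgzfError(
            f"no block starts at compressed offset {self.block_offset}"
        )


def _make_block(chunk: bytes) -> bytes:
    compressor = zlib.compressobj(
        zlib.Z_DEFAULT_COMPRESSION, zlib.DEFLATED, -15
    )
    cdata = compressor.compress(chunk) + compressor.flush()
    bsize = len(cdata) + 25  # header(18) + cdata + crc(4) + isize(4) - 1
    if bsize >= 1 << 16:
        raise BgzfError("compressed block exceeds 64 KiB")
    header = (
        _GZIP_MAGIC
        + bytes((8, 4))  # CM=deflate, FLG=FEXTRA
        + b"\x00\x00\x00\x00"  # MTIME
        + bytes((0, 0xFF))  # XFL, OS=unknown
        + struct.pack("<H", 6)  # XLEN
        + b"BC"
        + struct.pack("<HH", 2, bsize)
    )
    return header + cdata + struct.pack("<II", zlib.crc32(chunk), len(chunk))


def bgzf_compress(payload: bytes) -> bytes:
    """Compress *payload* into a complete BGZF stream (EOF block included).

    An empty payload yields the 28-byte EOF block alone.
    """
    out = bytearray()
    for i in range(0, len(payload), MAX_BLOCK_PAYLOAD):
        out += _make_block(payload[i : i + MAX_BLOCK_PAYLOAD])
    out += EOF_BLOCK
    return bytes(out)


def split_blocks(data: bytes) -> list[BgzfBlock]:
    """Parse a BGZF byte stream into its blocks without decompressing."""
    blocks: list[BgzfBlock] = []
    offset = 0
    n = len(data)
    while offset < n:
        if data[offset : offset + 2] != _GZIP_MAGIC:
            raise BgzfError(f"bad gzip magic at offset {offset}")
        if offset + 12 > n:
            raise BgzfError(f"truncated block header at offset {offset}")
        cm, flg = data[offset + 2], data[offset + 3]
        if cm != 8:
            raise BgzfError(f"unsupported compression method {cm}")
        if not flg & 4:
            raise BgzfError(
                f"block at {offset} has no extra field, so no BC subfield: "
                "not BGZF"
            )
        (xlen,) = struct.unpack_from("<H", data, offset + 10)
        extra = data[offset + 12 : offset + 12 + xlen]
        if len(extra) != xlen:
            raise BgzfError(f"truncated extra field at offset {offset}")
        bsize = None
        i = 0
        while i + 4 <= len(extra):
            si1, si2, slen = extra[i], extra[i + 1], struct.unpack_from(
                "<H", extra, i + 2
            )[0]
            if si1 == 0x42 and si2 == 0x43 and slen == 2:
                (bsize,) = struct.unpack_from("<H", extra, i + 4)
            i += 4 + slen
        if bsize is None:
            raise BgzfError(f"block at {offset} lacks the BC subfield")
        total = bsize + 1
        if offset + total > n:
            raise BgzfError(f"truncated block at offset {offset}")
        cdata = data[offset + 12 + xlen : offset + total - 8]
        crc, isize = struct.unpack_from("<II", data, offset + total - 8)
        blocks.append(BgzfBlock(offset, bsize, cdata, crc, isize))
        offset += total
    return blocks


def bgzf_decompress(
    data: bytes | IO[bytes],
    check_crc: bool = True,
    require_eof: bool = False,
) -> tuple[bytes, list[tuple[int, int]]]:
    """Inflate a BGZF stream.

    Returns the uncompressed concatenation and a block index of
    (compressed offset, uncompressed offset) pairs through which a
    :class:`VirtualOffset` resolves to an absolute position.  A missing
    EOF block warns by default and raises when ``require_eof`` is set.
    """
    if not isinstance(data, (bytes, bytearray)):
        data = data.read()
    blocks = split_blocks(bytes(data))
    out = bytearray()
    index: list[tuple[int, int]] = []
    for block in blocks:
        index.append((block.compressed_offset, len(out)))
        out += block.decompress(check_crc=check_crc)
    tail_ok = len(data) >= len(EOF_BLOCK) and bytes(
        data[-len(EOF_BLOCK):]
    ) == EOF_BLOCK
    if not tail_ok:
        if require_eof:
            raise BgzfError("stream does not end with the BGZF EOF block")
        warnings.warn(
            "BGZF stream does not end with the EOF block; it may be truncated",
            stacklevel=2,
        )
    return bytes(out), index
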