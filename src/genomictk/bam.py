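"""BAM: the binary, BGZF-wrapped encoding of SAM.

The uncompressed stream starts with the magic ``BAM\\1``, the SAM header
text, and the reference list; each alignment record then packs the eleven
mandatory fields into fixed-width integers, the CIGAR into 4-bit op codes
(order ``MIDNSHP=X``), the sequence into 4-bit nibbles over
``=ACMGRSVTWYHKDBN`` and the tags into typed binary values.

Decoding inverts all of that into the same :class:`~genomictk.sam.SamRecord`
objects the text parser produces, with the documented canonicalizations:
all integer tag widths (c, C, s, S, i, I) collapse to ``i`` and float tags
pass through float32.  The ``bin`` field is recomputed on write with the
standard region-to-bin function and ignored on read (no index support).
"""

from __future__ import annotations

import struct
from typing import IO, Iterable, Iterator

from .bgzf import bgzf_compress, bgzf_decompress
from .errors import FormatError
from .sam import Cigar, SamHeader, SamRecord, SamTag

BAM_MAGIC = b"BAM\x01"
_NIBBLE_BASES = "=ACMGRSVTWYHKDBN"
_BASE_TO_NIBBLE = {b: i for i, b in enumerate(_NIBBLE_BASES)}
_CIGAR_OPS = "MIDNSHP=X"
_INT_TAG_CODES = "cCsSiI"
_INT_TAG_STRUCTS = {
    "c": struct.Struct("<b"),
    "C": struct.Struct("<B"),
    "s": struct.Struct("<h"),
    "S": struct.Struct("<H"),
    "i": struct.Struct("<i"),
    "I": struct.Struct("<I"),
    "f": struct.Struct("<f"),
}


def reg2bin(beg: int, end: int) -> int:
    """The standard BAM region-to-bin function over [beg, end)."""
    end -= 1
    if beg >> 14 == end >> 14:
        return ((1 << 15) - 1) // 7 + (beg >> 14)
    if beg >> 17 == end >> 17:
        return ((1 << 12) - 1) // 7 + (beg >> 17)
    if beg >> 20 == end >> 20:
        return ((1 << 9) - 1) // 7 + (beg >> 20)
    if beg >> 23 == end >> 23:
        return ((1 << 6) - 1) // 7 + (beg >> 23)
    if beg >> 26 == end >> 26:
        return ((1 << 3) - 1) // 7 + (beg >> 26)
    return 0


def _encode_seq(seq: str) -> bytes:
    out = bytearray((len(seq) + 1) // 2)
    for i, base in enumerate(seq):
        try:
            nib = _BASE_TO_NIBBLE[base]
        except KeyError:
            raise FormatError(
                f"base {base!r} cannot be 4-bit encoded"
            ) from None
        if i % 2 == 0:
            out[i // 2] = nib << 4
        else:
            out[i // 2] |= nib
    return bytes(out)


def _decode_seq(data: bytes, l_seq: int) -> str:
    bases = []
    for i in range(l_seq):
        byte = data[i // 2]
        nib = byte >> 4 if i % 2 == 0 else byte & 0xF
        bases.append(_NIBBLE_BASES[nib])
    return "".join(bases)


def _encode_tags(tags: Iterable[SamTag]) -> bytes:
    out = bytearray()
    for t in tags:
        out += t.tag.encode("ascii")
        if t.type == "A":
            out += b"A" + str(t.value).encode("ascii")
        elif t.type == "i":
            v = int(t.value)
            if not -(1 << 31) <= v < 1 << 31:
                raise FormatError(f"tag {t.tag}: {v} exceeds int32")
            out += b"i" + _INT_TAG_STRUCTS["i"].pack(v)
        elif t.type == "f":
            out += b"f" + _INT_TAG_STRUCTS["f"].pack(float(t.value))
        elif t.type in ("Z", "H"):
            out += t.type.encode("ascii")
            out += str(t.value).encode("ascii") + b"\x00"
        elif t.type == "B":
            subtype, values = t.value
            st = _INT_TAG_STRUCTS[subtype]
            out += b"B" + subtype.encode("ascii")
            out += struct.pack("<I", len(values))
            for v in values:
                out += st.pack(v)
        else:
            raise FormatError(f"tag {t.tag}: unknown type {t.type!r}")
    return bytes(out)


def _decode_tags(data: bytes) -> tuple[SamTag, ...]:
    tags: list[SamTag] = []
    i = 0
    n = len(data)
    while i < n:
        if i + 3 > n:
            raise FormatError("truncated tag block")
        tag = data[i : i + 2].decode("ascii")
        code = chr(data[i + 2])
        i += 3
        if code == "A":
            tags.append(SamTag(tag, "A", chr(data[i])))
            i += 1
        elif code in _INT_TAG_CODES:
            st = _INT_TAG_STRUCTS[code]
            (v,) = st.unpack_from(data, i)
            i += st.size
            tags.append(SamTag(tag, "i", v))  # canonical integer type
        elif code == "f":
            (v,) = _INT_TAG_STRUCTS["f"].unpack_from(data, i)
            i += 4
            tags.append(SamTag(tag, "f", v))
        elif code in ("Z", "H"):
            end = data.index(b"\x00", i)
            tags.append(SamTag(tag, code, data[i:end].decode("ascii")))
            i = end + 1
        elif code == "B":
            subtype = chr(data[i])
            (count,) = struct.unpack_from("<I", data, i + 1)
            i += 5
            st = _INT_TAG_STRUCTS[subtype]
            values = tuple(
                st.unpack_from(data, i + k * st.size)[0] for k in range(count)
            )
            i += count * st.size
            tags.append(SamTag(tag, "B", (subtype, values)))
        else:
            raise FormatError(f"tag {tag}: unknown binary type {code!r}")
    return tuple(tags)


def _encode_record(rec: SamRecord, ref_ids: dict[str, int]) -> bytes:
    if rec.rname is None:
        ref_id = -1
    else:
        try:
            ref_id = ref_ids[rec.rname]
        except KeyError:
            raise FormatError(
                f"unknown-reference error: {rec.rname!r} has no @SQ line"
            ) from None
    next_ref_id = -1
    if rec.rnext is not None:
        rnext = rec.rname if rec.rnext == "=" else rec.rnext
        if rnext is None or rnext not in ref_ids:
            raise FormatError(f"unknown-reference error: {rec.rnext!r}")
        next_ref_id = ref_ids[rnext]
    pos0 = rec.pos - 1  # 1-based with 0-for-unmapped -> 0-based with -1
    name = rec.qname.encode("ascii") + b"\x00"
    cigar_ops = rec.cigar.ops if rec.cigar is not None else ()
    l_seq = len(rec.seq) if rec.seq is not None else 0
    if rec.cigar is not None and pos0 >= 0:
        bam_bin = reg2bin(pos0, pos0 + max(1, rec.cigar.reference_span()))
    else:
        bam_bin = reg2bin(max(pos0, 0), max(pos0, 0) + 1)
    body = bytearray()
    body += struct.pack(
        "<iiBBHHHiiii",
        ref_id,
        pos0,
        len(name),
        rec.mapq,
        bam_bin,
        len(cigar_ops),
        rec.flag,
        l_seq,
        next_ref_id,
        rec.pnext - 1,
        rec.tlen,
    )
    body += name
    for length, op in cigar_ops:
        body += struct.pack("<I", (length << 4) | _CIGAR_OPS.index(op))
    if rec.seq is not None:
        body += _encode_seq(rec.seq)
        if rec.qual is not None:
            body += bytes(ord(c) - 33 for c in rec.qual)
        else:
            body += b"\xff" * l_seq
    body += _encode_tags(rec.tags)
    return struct.pack("<I", len(body)) + bytes(body)


def _decode_record(
    data: bytes, offset: int, ref_names: tuple[str, ...], ordinal: int
) -> tuple[SamRecord, int]:
    try:
        (block_size,) = struct.unpack_from("<I", data, offset)
    except struct.error:
        raise FormatError(f"truncated record {ordinal}") from None
    start = offset + 4
    end = start + block_size
    if end > len(data):
        raise FormatError(f"truncated record {ordinal}")
    (
        ref_id,
        pos0,
        l_read_name,
        mapq,
        _bin,
        n_cigar_op,
        flag,
        l_seq,
        next_ref_id,
        next_pos0,
        tlen,
    ) = struct.unpack_from("<iiBBHHHiiii", data, start)
    for rid in (ref_id, next_ref_id):
        if rid != -1 and not 0 <= rid < len(ref_names):
            raise FormatError(
                f"record {ordinal}: reference ID {rid} out of range"
            )
    i = start + 32
    qname = data[i : i + l_read_name - 1].decode("ascii")
    i += l_read_name
    ops = []
    for _ in range(n_cigar_op):
        (packed,) = struct.unpack_from("<I", data, i)
        ops.append((packed >> 4, _CIGAR_OPS[packed & 0xF]))
        i += 4
    seq = qual = None
    if l_seq:
        seq = _decode_seq(data[i : i + (l_seq + 1) // 2], l_seq)
        i += (l_seq + 1) // 2
        quals = data[i : i + l_seq]
        i += l_seq
        if any(q != 0xFF for q in quals):
            qual = "".join(chr(q + 33) for q in quals)
    tags = _decode_tags(data[i:end])
    rec = SamRecord(
        qname=qname,
        flag=flag,
        rname=ref_names[ref_id] if ref_id != -1 else None,
        pos=pos0 + 1,
        mapq=mapq,
        cigar=Cigar(tuple(ops)) if ops else None,
        rnext=ref_names[next_ref_id] if next_ref_id != -1 else None,
        pnext=next_pos0 + 1,
        tlen=tlen,
        seq=seq,
        qual=qual,
        tags=tags,
    )
    return rec, end


def write_bam(header: SamHeader, records: Iterable[SamRecord]) -> bytes:
    """Serialize to a complete BGZF-wrapped BAM byte stream."""
    text = header.to_text().encode("ascii")
    refs = [(line.get("SN"), int(line.get("LN") or 0))
            for line in header.lines if line.record_type == "SQ"]
    ref_ids = {name: i for i, (name, _) in enumerate(refs)}
    payload = bytearray()
    payload += BAM_MAGIC
    payload += struct.pack("<i", len(text))
    payload += text
    payload += struct.pack("<i", len(refs))
    for name, length in refs:
        encoded = (name or "").encode("ascii") + b"\x00"
        payload += struct.pack("<i", len(encoded)) + encoded
        payload += struct.pack("<i", length)
    for rec in records:
        payload += _encode_record(rec, ref_ids)
    return bgzf_compress(bytes(payload))


def read_bam(
    source: bytes | IO[bytes], check_crc: bool = True
) -> tuple[SamHeader, Iterator[SamRecord]]:
    """Decode a BAM byte stream into a header and an iterator of records."""
    data, _ = bgzf_decompress(source, check_crc=check_crc)
    if data[:4] != BAM_MAGIC:
        raise FormatError(
            f"bad-magic error: expected BAM\\x01, got {data[:4]!r}"
        )
    (l_text,) = struct.unpack_from("<i", data, 4)
    text = data[8 : 8 + l_text].decode("ascii")
    i = 8 + l_text
    (n_ref,) = struct.unpack_from("<i", data, i)
    i += 4
    names: list[str] = []
    for _ in range(n_ref):
        (l_name,) = struct.unpack_from("<i", data, i)
        names.append(data[i + 4 : i + 4 + l_name - 1].decode("ascii"))
        i += 4 + l_name + 4
    header = SamHeader.parse(
        [ln for ln in text.splitlines() if ln]
    )
    ref_names = tuple(names)
    body_start = i

    def records() -> Iterator[SamRecord]:
        offset = body_start
        ordinal = 0
        while offset < len(data):
            rec, offset = _decode_record(data, offset, ref_names, ordinal)
            ordinal += 1
            yield rec

    return header, records()
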