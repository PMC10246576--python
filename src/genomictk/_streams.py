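"""Stream helpers: transparent gzip sniffing on read, path-or-stream duality."""

from __future__ import annotations

import gzip
import io
import sys
from contextlib import contextmanager
from typing import IO, Iterator, TextIO

_GZIP_MAGIC = b"\x1f\x8b"


@contextmanager
def open_text(source: str | TextIO, mode: str = "r") -> Iterator[TextIO]:
    """Open a path (plain or gzip-compressed on read) or pass a stream through.

    ``"-"`` denotes stdin/stdout.
    """
    if not isinstance(source, str):
        yield source
        return
    if source == "-":
        yield sys.stdin if "r" in mode else sys.stdout
        return
    if "r" in mode:
        with open(source, "rb") as raw:
            head = raw.read(2)
            raw.seek(0)
            if head == _GZIP_MAGIC:
                with gzip.open(raw, "rt") as fh:
                    yield fh
            else:
                yield io.TextIOWrapper(raw)
    else:
        with open(source, mode) as fh:
            yield fh


@contextmanager
def open_binary(source: str | IO[bytes], mode: str = "rb") -> Iterator[IO[bytes]]:
    """Open a path in binary mode or pass a binary stream through."""
    if not isinstance(source, str):
        yield source
        return
    if source == "-":
        yield sys.stdin.buffer if "r" in mode else sys.stdout.buffer
        return
    with open(source, mode) as fh:
        yield fh
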