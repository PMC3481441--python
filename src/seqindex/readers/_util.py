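"""Shared helpers for byte-accurate bank-file streaming.

All readers work on *binary* streams so that source offsets are true byte
offsets regardless of text encoding.  Text is decoded as UTF-8 with a
Latin-1 fallback (legacy banks are frequently Latin-1).
"""

from __future__ import annotations

from typing import IO, Iterator, Tuple


def decode(raw: bytes) -> str:
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def lines_with_offsets(stream: IO[bytes]) -> Iterator[Tuple[int, bytes]]:
    """Yield (byte_offset, raw_line) pairs; lines keep their newline."""
    offset = 0
    for raw in stream:
        yield offset, raw
        offset += len(raw)


def content_end(offset: int, raw: bytes) -> int:
    """Byte offset just past the last non-newline byte of *raw*."""
    return offset + len(raw.rstrip(b"\r\n"))


def ensure_binary(stream) -> IO[bytes]:
    """Readers require binary streams; fail fast on text-mode handles."""
    if hasattr(stream, "mode") and "b" not in getattr(stream, "mode", "b"):
        raise TypeError("readers require binary streams (open with 'rb')")
    return stream
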