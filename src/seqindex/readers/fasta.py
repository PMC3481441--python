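"""FASTA reader.

One record per ``>`` header.  Fields: ``id`` (first header token),
``description`` (remainder of the header, when present) and ``length``
(residue count).  The payload is the concatenated sequence, uppercased with
line breaks stripped, destined for the chunk store.  The source location
covers the header byte through the last sequence byte of the record.
"""

from __future__ import annotations

from typing import IO, Iterator

from ..errors import MalformedInputError
from ..model import ContentTypeRegistry, SourceLocation, make_document
from .base import ParsedRecord
from ._util import content_end, decode, ensure_binary, lines_with_offsets

CONTENT_TYPE = "biosequence/fasta"


def parse_fasta(
    stream: IO[bytes],
    path: str,
    *,
    registry: ContentTypeRegistry | None = None,
    _base_offset: int = 0,
) -> Iterator[ParsedRecord]:
    ensure_binary(stream)
    header: str | None = None
    start = 0
    end = 0
    seq_parts: list[bytes] = []

    def flush() -> ParsedRecord:
        assert header is not None
        toks = header.split(None, 1)
        rid = toks[0] if toks else ""
        if not rid:
            raise MalformedInputError(f"{path}: empty FASTA header at byte {start}")
        payload = b"".join(seq_parts).upper()
        fields: dict = {"id": rid, "length": len(payload)}
        if len(toks) > 1 and toks[1].strip():
            fields["description"] = toks[1].strip()
        loc = SourceLocation(path=path, offset=start, length=max(1, end - start))
        doc = make_document(fields, CONTENT_TYPE, loc, registry=registry)
        return ParsedRecord(document=doc, payload=payload, payload_id=doc.doc_id)

    for off, raw in lines_with_offsets(stream):
        off += _base_offset
        line = raw.rstrip(b"\r\n")
        if line.startswith(b">"):
            if header is not None:
                yield flush()
            header = decode(line[1:]).strip()
            start = off
            end = content_end(off, raw)
            seq_parts = []
        elif line.strip():
            if header is None:
                raise MalformedInputError(
                    f"{path}: sequence data before first FASTA header at byte {off}"
                )
            seq_parts.append(bytes(line.strip().replace(b" ", b"")))
            end = content_end(off, raw)
    if header is not None:
        yield flush()
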