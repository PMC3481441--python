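"""EMBL flat-file reader.

Line-code mapping mirrors the GenBank reader: ``ID`` → locus + length,
``AC`` → accession, ``DE`` (continuations joined with one space) →
definition, ``OS`` → organism, the ``FT`` table explodes into per-feature
documents under the same switch as GenBank, and the ``SQ`` block becomes
the sequence payload (uppercased, counts stripped).
"""

from __future__ import annotations

import re
from typing import IO, Iterator

from ..errors import TruncatedRecordError
from ..model import ContentTypeRegistry, SourceLocation, Value, make_document
from .base import ParsedRecord
from .genbank import _explode_features
from ._util import content_end, decode, ensure_binary, lines_with_offsets

CONTENT_TYPE = "biosequence/embl"

_BP = re.compile(r"(\d+)\s+BP", re.IGNORECASE)


def parse_embl(
    stream: IO[bytes],
    path: str,
    *,
    registry: ContentTypeRegistry | None = None,
    explode_features: bool = True,
) -> Iterator[ParsedRecord]:
    ensure_binary(stream)
    record: list[str] = []
    start = None
    end = 0
    for off, raw in lines_with_offsets(stream):
        line = decode(raw.rstrip(b"\r\n"))
        if start is None:
            if not line.strip():
                continue
            start = off
        record.append(line)
        end = content_end(off, raw)
        if line.strip() == "//":
            loc = SourceLocation(path=path, offset=start, length=end - start)
            yield from _emit_record(record, loc, registry, explode_features)
            record, start = [], None
    if record and any(l.strip() for l in record):
        raise TruncatedRecordError(f"{path}: record without '//' terminator")


def _emit_record(
    lines: list[str],
    loc: SourceLocation,
    registry: ContentTypeRegistry | None,
    explode_features: bool,
) -> Iterator[ParsedRecord]:
    fields: dict[str, Value | list[str]] = {}
    definition: list[str] = []
    feature_lines: list[str] = []
    seq_parts: list[str] = []
    in_seq = False
    for line in lines:
        code = line[:2]
        body = line[5:] if len(line) > 5 else ""
        if code == "ID":
            toks = body.replace(";", " ").split()
            if toks:
                fields["locus"] = toks[0]
            m = _BP.search(body)
            if m:
                fields["length"] = int(m.group(1))
        elif code == "AC":
            acc = body.split(";")[0].strip()
            if acc and "accession" not in fields:
                fields["accession"] = acc
        elif code == "DE":
            definition.append(body.strip())
        elif code == "OS" and "organism" not in fields:
            fields["organism"] = body.strip().rstrip(".")
        elif code == "FT":
            # re-shape to GenBank geometry: key at col 5, qualifiers at col 21
            feature_lines.append("     " + line[5:21].ljust(16) + line[21:])
        elif code == "SQ":
            in_seq = True
        elif code == "  " and in_seq:
            seq_parts.append("".join(c for c in line if c.isalpha()))
        elif code == "//":
            break
    if definition and any(definition):
        fields["definition"] = " ".join(d for d in definition if d)
    accession = str(fields.get("accession", fields.get("locus", "")))
    payload = "".join(seq_parts).upper().encode("ascii")
    doc = make_document(fields, CONTENT_TYPE, loc, registry=registry,
                        doc_id=accession or None)
    yield ParsedRecord(document=doc, payload=payload if payload else None,
                       payload_id=doc.doc_id if payload else None)
    if explode_features and feature_lines:
        yield from _explode_features(feature_lines, accession or doc.doc_id,
                                     loc, registry)
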