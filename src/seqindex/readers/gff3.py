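"""GFF3 reader.

One Document per feature line, content type ``biosequence/gff``.  Column
fields: seqid, source_tag, type, start, end, score, strand, phase ('.'
placeholders are omitted); every attribute key becomes a field, with
comma-separated attribute values expanded to multi-valued fields per the
GFF3 convention, and %XX escapes decoded.  A line with the wrong column
count is a recoverable per-line error: skipped and reported through
*on_error* (default: logged).

An embedded ``##FASTA`` section is parsed as FASTA; those records carry
their sequence payloads keyed by their first header token (the seqid), so
the region driver can serve reference sequence for the features above.
"""

from __future__ import annotations

import itertools
import urllib.parse
from typing import Callable, IO, Iterator, Optional

from ..model import ContentTypeRegistry, SourceLocation, Value, make_document
from .base import ParsedRecord, log
from .fasta import parse_fasta
from ._util import content_end, decode, ensure_binary, lines_with_offsets

CONTENT_TYPE = "biosequence/gff"

COLUMN_FIELDS = ("seqid", "source_tag", "type", "start", "end", "score", "strand", "phase")


def _maybe_num(s: str, as_int: bool) -> Value:
    try:
        return int(s) if as_int else float(s)
    except ValueError:
        return s


def parse_attributes(col9: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for part in col9.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, raw = part.partition("=")
        values = [urllib.parse.unquote(v) for v in raw.split(",")] if raw else [""]
        attrs.setdefault(key.strip(), []).extend(values)
    return attrs


def parse_gff3(
    stream: IO[bytes],
    path: str,
    *,
    registry: ContentTypeRegistry | None = None,
    on_error: Optional[Callable[[int, str], None]] = None,
) -> Iterator[ParsedRecord]:
    ensure_binary(stream)
    if on_error is None:
        on_error = lambda off, msg: log.warning("%s: byte %d: %s", path, off, msg)

    it = lines_with_offsets(stream)
    for off, raw in it:
        line = decode(raw.rstrip(b"\r\n"))
        if not line.strip():
            continue
        if line.startswith("##FASTA"):
            # remainder of the file is reference sequence in FASTA form
            base = off + len(raw)
            yield from parse_fasta(stream, path, registry=registry, _base_offset=base)
            return
        if line.startswith(">"):
            # a bare '>' implies the FASTA section (pragma is optional)
            yield from parse_fasta(itertools.chain([raw], stream), path,
                                   registry=registry, _base_offset=off)
            return
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            on_error(off, f"expected 9 tab-separated columns, got {len(cols)}")
            continue
        fields: dict[str, Value | list[str]] = {}
        for name, value in zip(COLUMN_FIELDS, cols[:8]):
            if value == ".":
                continue
            if name in ("start", "end"):
                fields[name] = _maybe_num(value, as_int=True)
            elif name == "score":
                fields[name] = _maybe_num(value, as_int=False)
            elif name == "phase":
                fields[name] = _maybe_num(value, as_int=True)
            else:
                fields[name] = value
        if cols[8].strip() and cols[8].strip() != ".":
            for key, values in parse_attributes(cols[8]).items():
                fields.setdefault(key, values)
        loc = SourceLocation(path=path, offset=off,
                             length=content_end(off, raw) - off)
        doc = make_document(fields, CONTENT_TYPE, loc, registry=registry)
        yield ParsedRecord(document=doc)
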