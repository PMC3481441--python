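"""GenBank flat-file reader.

Each record (terminated by ``//``) yields a header Document with fields
locus, accession, version, definition, organism, length and the ORIGIN
sequence as payload (uppercased, position numbers and whitespace stripped —
ORIGIN formatting is presentation, not data).

With feature explosion enabled (the default) every feature-table entry
additionally yields its own Document with content type ``biosequence/gff``
(fields: seqid := accession, type := feature key, start, end, strand, plus
qualifiers), so GenBank features answer genome-browser region queries
exactly like native GFF features.  ``/translation`` qualifier values are
large and sequence-like, so they are stored as separate payloads keyed
``<doc_id>:translation`` rather than as fields.

All documents of a record share the record's byte span as source location:
the whole record is the smallest slice that re-parses standalone.
"""

from __future__ import annotations

from typing import IO, Iterator

from ..errors import TruncatedRecordError
from ..model import ContentTypeRegistry, SourceLocation, Value, make_document
from .base import ParsedRecord
from .location import parse_location
from ._util import content_end, decode, ensure_binary, lines_with_offsets

CONTENT_TYPE = "biosequence/genbank"
FEATURE_CONTENT_TYPE = "biosequence/gff"

_HEADER_KEYWORDS = ("LOCUS", "DEFINITION", "ACCESSION", "VERSION", "KEYWORDS",
                    "SOURCE", "REFERENCE", "COMMENT", "DBLINK")


def _parse_qualifiers(lines: list[str]) -> dict[str, list[str]]:
    """Parse ``/key="value"`` qualifier lines (values may span lines)."""
    quals: dict[str, list[str]] = {}
    key = None
    buf: list[str] = []
    open_quote = False

    def flush() -> None:
        nonlocal key, buf
        if key is not None:
            value = " ".join(buf).strip()
            if value.startswith('"') and value.endswith('"') and len(value) >= 2:
                value = value[1:-1]
            if key == "translation":
                value = value.replace(" ", "")
            quals.setdefault(key, []).append(value if value else "true")
        key, buf = None, []

    for line in lines:
        stripped = line.strip()
        if stripped.startswith("/") and not open_quote:
            flush()
            k, eq, v = stripped[1:].partition("=")
            key = k.strip()
            buf = [v.strip()] if eq else []
            open_quote = bool(eq) and v.strip().count('"') == 1
        else:
            buf.append(stripped)
            if open_quote and stripped.count('"') % 2 == 1:
                open_quote = False
    flush()
    return quals


def _explode_features(
    feature_lines: list[str],
    accession: str,
    loc: SourceLocation,
    registry: ContentTypeRegistry | None,
    key_col: int = 5,
    qual_col: int = 21,
) -> Iterator[ParsedRecord]:
    # group the indented table into (key, location+qualifier lines) entries
    entries: list[tuple[str, list[str]]] = []
    for line in feature_lines:
        body = line[key_col:]
        key = body[: qual_col - key_col].strip()
        rest = line[qual_col:] if len(line) > qual_col else ""
        if key:
            entries.append((key, [rest]))
        elif entries:
            entries[-1][1].append(rest)
    for i, (key, lines) in enumerate(entries):
        # location may continue over lines until the first qualifier
        loc_parts: list[str] = []
        qual_lines: list[str] = []
        for ln in lines:
            if qual_lines or ln.strip().startswith("/"):
                qual_lines.append(ln)
            else:
                loc_parts.append(ln.strip())
        span = parse_location("".join(loc_parts))
        fields: dict[str, Value | list[str]] = {
            "seqid": accession,
            "type": key,
            "start": span.start,
            "end": span.end,
            "strand": span.strand,
        }
        if not span.exact:
            fields["location_exact"] = "false"
        quals = _parse_qualifiers(qual_lines)
        translation = quals.pop("translation", None)
        for qk, qv in quals.items():
            fields.setdefault(qk, qv)
        doc_id = f"{accession}:f{i}"
        doc = make_document(fields, FEATURE_CONTENT_TYPE, loc,
                            registry=registry, doc_id=doc_id)
        payload = translation[0].encode("ascii") if translation else None
        yield ParsedRecord(
            document=doc,
            payload=payload,
            payload_id=f"{doc_id}:translation" if payload else None,
        )


def parse_genbank(
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
    feature_lines: list[str] = []
    seq_parts: list[str] = []
    section = None
    definition: list[str] = []
    for line in lines:
        kw = line[:12].strip()
        if line.startswith("LOCUS"):
            toks = line.split()
            if len(toks) >= 2:
                fields["locus"] = toks[1]
            if len(toks) >= 4 and toks[3] in ("bp", "aa") and toks[2].isdigit():
                fields["length"] = int(toks[2])
            section = "header"
        elif line.startswith("DEFINITION"):
            definition = [line[12:].strip()]
            section = "definition"
        elif line.startswith("ACCESSION"):
            toks = line.split()
            if len(toks) >= 2:
                fields["accession"] = toks[1]
            section = "header"
        elif line.startswith("VERSION"):
            toks = line.split()
            if len(toks) >= 2:
                fields["version"] = toks[1]
            section = "header"
        elif line.strip().startswith("ORGANISM") and "organism" not in fields:
            fields["organism"] = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else ""
            section = "header"
        elif line.startswith("FEATURES"):
            section = "features"
        elif line.startswith("ORIGIN"):
            section = "origin"
        elif line.strip() == "//":
            break
        elif section == "definition" and line.startswith(" "):
            definition.append(line.strip())
        elif section == "features" and line.startswith(" "):
            feature_lines.append(line)
        elif section == "origin":
            seq_parts.append("".join(c for c in line if c.isalpha()))
        elif line[:1] not in (" ", ""):
            section = "header"  # other top-level keywords (KEYWORDS, SOURCE...)
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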