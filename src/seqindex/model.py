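"""Shared document/field/schema/content-type data model.

Every indexed unit is a :class:`Document`: a mapping of field names to
ordered lists of values (strings or numbers), tagged with a
``biosequence/<format>`` content type and, for records parsed from a bank
file, a :class:`SourceLocation` giving the exact byte span of the original
record.  Byte spans let any search result link back to — and byte-for-byte
reproduce — the flat-file record it came from.

Field semantics are declared in a :class:`Schema`: a field may be *indexed*
(usable as a query filter), *stored* (returned with results), or both.  The
schema is open by default: undeclared fields behave as
``{kind: text, indexed: true, stored: true}``, because bank formats carry
unpredictable qualifier keys.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field as dc_field
from typing import IO, Iterable, Mapping, Sequence, Union

import yaml

from .errors import (
    ContentTypeConflictError,
    SchemaError,
    UnknownContentTypeError,
)

Value = Union[str, int, float]

_CONTENT_TYPE_RE = re.compile(r"^biosequence/[A-Za-z0-9_+.-]+$")

FIELD_KINDS = ("text", "keyword", "numeric")


@dataclass(frozen=True)
class SourceLocation:
    """Provenance of a record: bytes ``[offset, offset+length)`` of *path*.

    Offsets are always bytes, never characters; reading that slice back
    reproduces the record text verbatim.
    """

    path: str
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")


@dataclass(frozen=True)
class ContentTypeDescriptor:
    """What a content type means to the front end."""

    renderer: str = "generic"
    region_queryable: bool = False


class ContentTypeRegistry:
    """Registry of ``biosequence/<format>`` content types.

    Lookup of an unregistered type is an error; duplicate registration with
    an identical descriptor is an idempotent no-op.
    """

    def __init__(self) -> None:
        self._types: dict[str, ContentTypeDescriptor] = {}

    def register(self, name: str, descriptor: ContentTypeDescriptor | None = None) -> None:
        descriptor = descriptor or ContentTypeDescriptor()
        if not _CONTENT_TYPE_RE.match(name):
            raise UnknownContentTypeError(
                f"content type must match 'biosequence/<token>': {name!r}"
            )
        existing = self._types.get(name)
        if existing is not None and existing != descriptor:
            raise ContentTypeConflictError(
                f"content type {name!r} already registered with a different descriptor"
            )
        self._types[name] = descriptor

    def lookup(self, name: str) -> ContentTypeDescriptor:
        try:
            return self._types[name]
        except KeyError:
            raise UnknownContentTypeError(f"unregistered content type: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def names(self) -> list[str]:
        return sorted(self._types)


def default_registry() -> ContentTypeRegistry:
    """Registry preloaded with the built-in bank formats."""
    reg = ContentTypeRegistry()
    reg.register("biosequence/fasta", ContentTypeDescriptor("sequence", False))
    reg.register("biosequence/gff", ContentTypeDescriptor("browser", True))
    reg.register("biosequence/genbank", ContentTypeDescriptor("sequence", False))
    reg.register("biosequence/embl", ContentTypeDescriptor("sequence", False))
    reg.register("biosequence/pdb", ContentTypeDescriptor("structure", False))
    return reg


def _as_value_list(v: Value | Sequence[Value]) -> list[Value]:
    if isinstance(v, (str, int, float)) and not isinstance(v, bool):
        return [v]
    if isinstance(v, (list, tuple)):
        out: list[Value] = []
        for x in v:
            if isinstance(x, bool) or not isinstance(x, (str, int, float)):
                raise TypeError(f"field values must be str/int/float, got {x!r}")
            out.append(x)
        return out
    raise TypeError(f"field values must be str/int/float or lists thereof, got {v!r}")


@dataclass
class Document:
    """One indexed record: multi-valued key/value fields plus provenance.

    Multi-valued fields are ordered lists; a query matches if any value
    matches.
    """

    doc_id: str
    content_type: str
    fields: dict[str, list[Value]]
    source: SourceLocation | None = None

    def content_equal(self, other: "Document") -> bool:
        """Field-for-field equality ignoring identity and provenance.

        Used by the source-fidelity contract, where re-parsing a byte slice
        cannot reproduce the original absolute offset.
        """
        return self.content_type == other.content_type and self.fields == other.fields

    def first(self, name: str, default: Value | None = None) -> Value | None:
        vals = self.fields.get(name)
        return vals[0] if vals else default

    def to_json(self) -> dict:
        d: dict = {
            "doc_id": self.doc_id,
            "content_type": self.content_type,
            "fields": self.fields,
        }
        if self.source is not None:
            d["source"] = {
                "path": self.source.path,
                "offset": self.source.offset,
                "length": self.source.length,
            }
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "Document":
        src = d.get("source")
        return cls(
            doc_id=d["doc_id"],
            content_type=d["content_type"],
            fields={k: list(v) for k, v in d["fields"].items()},
            source=SourceLocation(**src) if src else None,
        )


def fallback_doc_id(path: str, offset: int, extra: str = "") -> str:
    """Deterministic hex id for records without an explicit id field.

    Stable across re-indexing runs of the same bank file.
    """
    h = hashlib.sha1(f"{path}\x00{offset}\x00{extra}".encode("utf-8"))
    return h.hexdigest()[:16]


def make_document(
    fields: Mapping[str, Value | Sequence[Value]],
    content_type: str,
    source: SourceLocation | None = None,
    *,
    registry: ContentTypeRegistry | None = None,
    doc_id: str | None = None,
) -> Document:
    """Build a Document from a key/value field map.

    The doc_id comes from an ``id`` field if present, else from *doc_id*,
    else from a deterministic hash of the source path+offset.
    """
    registry = registry or default_registry()
    registry.lookup(content_type)
    if not fields:
        raise ValueError("document must have at least one field")
    norm = {k: _as_value_list(v) for k, v in fields.items()}
    if doc_id is None:
        if "id" in norm and norm["id"]:
            doc_id = str(norm["id"][0])
        elif source is not None:
            doc_id = fallback_doc_id(source.path, source.offset)
        else:
            raise ValueError("cannot assign doc_id: no 'id' field and no source location")
    return Document(doc_id=doc_id, content_type=content_type, fields=norm, source=source)


@dataclass(frozen=True)
class FieldSchema:
    """Per-field declaration: kind plus indexed/stored flags."""

    name: str
    kind: str = "text"
    indexed: bool = True
    stored: bool = True

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise SchemaError(f"unknown field kind {self.kind!r} for {self.name!r}")
        if not self.indexed and not self.stored:
            raise SchemaError(
                f"field {self.name!r} must be indexed or stored (or both)"
            )


# undeclared fields in an open schema behave like this
OPEN_DEFAULT = FieldSchema(name="*", kind="text", indexed=True, stored=True)


class Schema:
    """A set of field declarations with an open-schema default."""

    def __init__(self, fields: Iterable[FieldSchema] = (), open_schema: bool = True):
        self._fields: dict[str, FieldSchema] = {}
        self.open_schema = open_schema
        for f in fields:
            if f.name in self._fields:
                raise SchemaError(f"duplicate field declaration: {f.name!r}")
            self._fields[f.name] = f

    def field(self, name: str) -> FieldSchema:
        f = self._fields.get(name)
        if f is not None:
            return f
        if not self.open_schema:
            raise SchemaError(f"field {name!r} not declared in closed schema")
        return FieldSchema(name=name, kind=OPEN_DEFAULT.kind,
                           indexed=OPEN_DEFAULT.indexed, stored=OPEN_DEFAULT.stored)

    def declared(self) -> list[FieldSchema]:
        return list(self._fields.values())

    def __contains__(self, name: str) -> bool:
        return name in self._fields


def default_bank_schema() -> Schema:
    """Schema the CLI uses when none is supplied.

    Declares the coordinate/size fields the built-in readers emit as
    numeric (so ranged queries compare numbers, not strings); everything
    else falls through to the open-schema text default.
    """
    numeric = ("start", "end", "length", "score", "phase")
    return Schema([FieldSchema(name=n, kind="numeric") for n in numeric])


def load_schema(config: Union[str, IO[str]]) -> Schema:
    """Load a schema from a YAML (or JSON) config.

    The config is a list of ``{name, kind, indexed, stored}`` mappings;
    ``kind`` defaults to ``text``, both flags default to true.  An empty
    config yields an empty schema where the open-schema defaults apply.
    """
    if hasattr(config, "read"):
        text = config.read()
    else:
        with open(config, "r", encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if data is None:
        return Schema()
    if isinstance(data, Mapping) and "fields" in data:
        data = data["fields"]
    if not isinstance(data, list):
        raise SchemaError("schema config must be a list of field declarations")
    fields = []
    for entry in data:
        if not isinstance(entry, Mapping) or "name" not in entry:
            raise SchemaError(f"bad schema entry: {entry!r}")
        fields.append(
            FieldSchema(
                name=str(entry["name"]),
                kind=str(entry.get("kind", "text")),
                indexed=bool(entry.get("indexed", True)),
                stored=bool(entry.get("stored", True)),
            )
        )
    return Schema(fields)


def dump_document(doc: Document) -> str:
    """Serialize a Document to a JSON line (round-trips via load_document)."""
    return json.dumps(doc.to_json(), separators=(",", ":"))


def load_document(text: str) -> Document:
    return Document.from_json(json.loads(text))
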