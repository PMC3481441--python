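"""PDB reader: one Document per file.

Extracts the id and classification from the fixed columns of the HEADER
record, the joined TITLE, COMPND molecule names, SOURCE scientific
organism(s), and the deposition date.  The payload is the complete file
body so a structure viewer can be served the original bytes.
"""

from __future__ import annotations

from typing import IO, Iterator

from ..errors import MalformedInputError
from ..model import ContentTypeRegistry, SourceLocation, Value, make_document
from .base import ParsedRecord
from ._util import decode, ensure_binary

CONTENT_TYPE = "biosequence/pdb"


def _continued(records: list[str]) -> str:
    return " ".join(r.strip() for r in records if r.strip())


def parse_pdb(
    stream: IO[bytes],
    path: str,
    *,
    registry: ContentTypeRegistry | None = None,
) -> Iterator[ParsedRecord]:
    ensure_binary(stream)
    data = stream.read()
    if not data.strip():
        return
    text = decode(data)
    lines = text.splitlines()
    header = next((l for l in lines if l.startswith("HEADER")), None)
    if header is None:
        raise MalformedInputError(f"{path}: missing HEADER record")
    fields: dict[str, Value | list[str]] = {}
    pdb_id = header[62:66].strip()
    if pdb_id:
        fields["pdb_id"] = pdb_id
    classification = header[10:50].strip()
    if classification:
        fields["classification"] = classification
    dep_date = header[50:59].strip()
    if dep_date:
        fields["deposition_date"] = dep_date

    titles = [l[10:] for l in lines if l.startswith("TITLE")]
    if titles:
        fields["title"] = _continued(titles)
    molecules = []
    for l in lines:
        if l.startswith("COMPND") and "MOLECULE:" in l:
            molecules.append(l.split("MOLECULE:", 1)[1].strip().rstrip(";").strip())
        if l.startswith("SOURCE") and "ORGANISM_SCIENTIFIC:" in l and "organism" not in fields:
            fields["organism"] = l.split("ORGANISM_SCIENTIFIC:", 1)[1].strip().rstrip(";").strip()
    if molecules:
        fields["molecule"] = molecules

    loc = SourceLocation(path=path, offset=0, length=len(data))
    doc = make_document(fields, CONTENT_TYPE, loc, registry=registry,
                        doc_id=pdb_id or None)
    yield ParsedRecord(document=doc, payload=data, payload_id=doc.doc_id)
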