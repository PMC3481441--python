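"""Genome-browser adapter: region feature queries and region sequence.

Answers the two questions a browser asks: which features overlap
``seqid:start-end``, and what is the sequence there.  Feature lookup is an
index query (``seqid:<id> AND start:[* TO end] AND end:[start TO *]``)
restricted to ``biosequence/gff`` documents; overlap is closed-interval
intersection on the 1-based inclusive coordinates the source formats use.
Sequence retrieval hits the chunk store with the single 1-based→0-based
conversion in the code base: residues ``start..end`` are bytes
``[start-1, end)``.  Features are returned whole, never clipped — clipping
is a renderer concern.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .chunks import ChunkStore
from .errors import SeqIndexError, SubrangeError
from .index import Hit, Index
from .model import Document, Value
from .query import Bool, Range, Term
from .readers.gff3 import COLUMN_FIELDS
from .shards import ShardSet

GFF_CONTENT_TYPE = "biosequence/gff"


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval on a named reference sequence."""

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid region: need 1 <= start <= end, "
                             f"got {self.start}..{self.end}")


def features_in_region(
    searcher: Union[Index, ShardSet],
    region: Region,
    type_filter: Optional[str] = None,
) -> list[Hit]:
    """All biosequence/gff documents overlapping *region*.

    Overlap predicate: doc.start <= region.end AND doc.end >= region.start.
    Results ordered by (start asc, end asc, doc_id asc).
    """
    clauses = [
        Term("seqid", region.seqid.lower()),
        Range("start", None, region.end),
        Range("end", region.start, None),
    ]
    if type_filter:
        clauses.append(Term("type", type_filter.lower()))
    ast = Bool("AND", tuple(clauses))
    result = searcher.search(ast, 0, None)
    hits = [h for h in result.hits if h.content_type == GFF_CONTENT_TYPE]
    hits.sort(key=lambda h: (h.fields.get("start", [0])[0],
                             h.fields.get("end", [0])[0], h.doc_id))
    return hits


def sequence_of_region(store: ChunkStore, region: Region) -> str:
    """Residues *start..end* (1-based inclusive) of the stored reference."""
    total = store.length(region.seqid)  # raises UnknownKeyError if absent
    if region.end > total:
        raise SubrangeError(
            f"region end {region.end} beyond stored length {total} of "
            f"{region.seqid!r}"
        )
    return store.get(region.seqid, region.start - 1, region.end).decode("ascii")


def _fmt_col(values: Optional[list[Value]]) -> str:
    if not values:
        return "."
    v = values[0]
    if isinstance(v, float) and v == int(v):
        return str(v)
    return str(v)


def _escape_attr(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :^*$@!+?|")


def export_region_gff(features: Sequence[Union[Hit, Document]],
                      region: Optional[Region] = None) -> str:
    """Serialize features as GFF3 (round-trips through the GFF3 reader).

    Attributes are ordered ID, Name, Parent, then alphabetically; multi
    values are comma-joined; reserved characters are percent-encoded.
    """
    lines = ["##gff-version 3"]
    if region is not None:
        lines.append(f"##sequence-region {region.seqid} {region.start} {region.end}")
    for feat in features:
        fields = feat.fields
        doc_id = feat.doc_id
        for mandatory in ("seqid", "type", "start", "end"):
            if mandatory not in fields or not fields[mandatory]:
                raise SeqIndexError(
                    f"feature {doc_id!r} missing mandatory field {mandatory!r}"
                )
        cols = [
            _fmt_col(fields.get("seqid")),
            _fmt_col(fields.get("source_tag")),
            _fmt_col(fields.get("type")),
            str(fields["start"][0]),
            str(fields["end"][0]),
            _fmt_col(fields.get("score")),
            _fmt_col(fields.get("strand")),
            _fmt_col(fields.get("phase")),
        ]
        attr_keys = [k for k in fields if k not in COLUMN_FIELDS]
        head = [k for k in ("ID", "Name", "Parent") if k in attr_keys]
        rest = sorted(k for k in attr_keys if k not in ("ID", "Name", "Parent"))
        attrs = ";".join(
            f"{k}={','.join(_escape_attr(v) for v in fields[k])}"
            for k in head + rest
        )
        cols.append(attrs if attrs else ".")
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"
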