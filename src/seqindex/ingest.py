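"""Indexing pipeline: stream bank files into shards and the chunk store.

Used by both the offline CLI (write segments directly, commit at the end)
and the online path (POST documents to a running service, no restart).
Per-line recoverable errors (a bad GFF line) are skipped and reported;
per-record structural errors abort that record only — banks are large and
dirty, one bad line must not kill an ingest.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

from .chunks import ChunkStore
from .errors import IntegrityError, SeqIndexError
from .index import Index
from .model import Schema, SourceLocation
from .readers import ReaderRegistry, apply_recoders, default_reader_registry
from .readers.recode import RecoderRule
from .shards import route_document

log = logging.getLogger("seqindex.ingest")


@dataclass
class IndexJobReport:
    """Outcome of one indexing run; indexed + skipped = emitted."""

    files: int = 0
    emitted: int = 0
    indexed: int = 0
    skipped: int = 0
    skip_reasons: list[str] = dc_field(default_factory=list)
    payloads: int = 0
    elapsed_s: float = 0.0

    def to_json(self) -> dict:
        return {
            "files": self.files, "emitted": self.emitted,
            "indexed": self.indexed, "skipped": self.skipped,
            "skip_reasons": self.skip_reasons, "payloads": self.payloads,
            "elapsed_s": round(self.elapsed_s, 3),
        }


def index_files(
    fmt: str,
    paths: Sequence[str],
    indexes: Sequence[Index],
    store: Optional[ChunkStore] = None,
    *,
    registry: ReaderRegistry | None = None,
    recoders: Sequence[RecoderRule] = (),
    store_payloads: bool = True,
    update: bool = False,
    commit: bool = True,
) -> IndexJobReport:
    """Index *paths* of format *fmt* into *indexes* (sharded by doc_id hash).

    With ``update=True`` records whose doc_id already exists are routed
    through partial update instead of replacement.
    """
    registry = registry or default_reader_registry()
    reader = registry.get(fmt)  # raises KeyError listing available formats
    report = IndexJobReport()
    t0 = time.monotonic()
    n_shards = len(indexes)
    for path in paths:
        report.files += 1
        skips_here: list[str] = []

        def on_error(off: int, msg: str) -> None:
            skips_here.append(f"{path}@{off}: {msg}")

        kwargs = {"registry": registry.content_types}
        if fmt == "gff3":
            kwargs["on_error"] = on_error
        with open(path, "rb") as fh:
            for rec in reader(fh, path, **kwargs):
                report.emitted += 1
                doc = rec.document
                if recoders:
                    doc = apply_recoders(doc, recoders)
                ix = indexes[route_document(doc.doc_id, n_shards)]
                try:
                    if update and doc.doc_id in ix:
                        ix.update_document(doc.doc_id, doc.fields)
                    else:
                        ix.add_document(doc)
                    report.indexed += 1
                except SeqIndexError as e:
                    skips_here.append(f"{path}: doc {doc.doc_id}: {e}")
                    continue
                if store_payloads and store is not None and rec.payload is not None:
                    store.put(rec.payload_id or doc.doc_id, rec.payload)
                    report.payloads += 1
        report.emitted += len([s for s in skips_here if "@" in s])
        report.skipped += len(skips_here)
        report.skip_reasons.extend(skips_here)
    if commit:
        for ix in indexes:
            ix.commit()
    report.elapsed_s = time.monotonic() - t0
    return report


def open_shards(index_dir: str, n_shards: int, schema: Schema | None = None,
                create: bool = False) -> list[Index]:
    """Open (or create) ``n_shards`` segment directories under *index_dir*."""
    indexes = []
    for i in range(n_shards):
        path = os.path.join(index_dir, f"shard-{i}") if n_shards > 1 else index_dir
        if create:
            os.makedirs(path, exist_ok=True)
        indexes.append(Index(path=path, schema=schema))
    return indexes


def shard_paths(index_dir: str, n_shards: int) -> list[str]:
    if n_shards <= 1:
        return [index_dir]
    return [os.path.join(index_dir, f"shard-{i}") for i in range(n_shards)]


def fetch_original(source: SourceLocation) -> bytes:
    """Read back exactly the record bytes named by a source location.

    Raises :class:`IntegrityError` when the bank file has been truncated or
    moved since indexing.
    """
    try:
        with open(source.path, "rb") as fh:
            fh.seek(source.offset)
            data = fh.read(source.length)
    except OSError as e:
        raise IntegrityError(f"cannot read original file {source.path!r}: {e}") from e
    if len(data) != source.length:
        raise IntegrityError(
            f"{source.path!r}: expected {source.length} bytes at offset "
            f"{source.offset}, got {len(data)} (file changed?)"
        )
    return data
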