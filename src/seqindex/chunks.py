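"""Chunked key/value storage for large raw data.

A datum (chromosome sequence, PDB body, translation text) is stored under a
string key, split into fixed-size chunks; a read can name a byte subrange
``[start, stop)`` and only the chunks overlapping that window are touched —
that is the whole point: retrieving a gene from its position in a
chromosome must not reassemble the chromosome.  Subranges are 0-based,
stop-exclusive, in bytes; the 1-based inclusive biological convention is
translated exactly once, in the region driver.

Backends implement a four-method interface (put/get/delete/list of opaque
blobs) so embedded-file, in-memory and remote stores are interchangeable.
The reference backend is file-based: one directory per key (named by key
hash), a JSON meta blob plus numbered chunk files, overwritten atomically
(new generation written first, meta switched last).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass
from typing import Iterator, Optional, Protocol

from .errors import StoreError, SubrangeError, UnknownKeyError

log = logging.getLogger("seqindex.chunks")

DEFAULT_CHUNK_SIZE = 65536


@dataclass(frozen=True)
class ChunkRecord:
    """Metadata of one stored datum."""

    key: str
    total_length: int
    chunk_size: int
    n_chunks: int


class Backend(Protocol):
    def put_blob(self, key: str, name: str, data: bytes) -> None: ...
    def get_blob(self, key: str, name: str) -> bytes: ...
    def delete_blob(self, key: str, name: str) -> None: ...
    def delete_key(self, key: str) -> None: ...
    def list_keys(self) -> Iterator[str]: ...
    def has_key(self, key: str) -> bool: ...


class MemoryBackend:
    """Dict-backed store; used for tests and ephemeral services."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, bytes]] = {}

    def put_blob(self, key: str, name: str, data: bytes) -> None:
        self._data.setdefault(key, {})[name] = data

    def get_blob(self, key: str, name: str) -> bytes:
        try:
            return self._data[key][name]
        except KeyError:
            raise StoreError(f"missing blob {name!r} for key {key!r}") from None

    def delete_blob(self, key: str, name: str) -> None:
        self._data.get(key, {}).pop(name, None)

    def delete_key(self, key: str) -> None:
        self._data.pop(key, None)

    def list_keys(self) -> Iterator[str]:
        return iter(list(self._data))

    def has_key(self, key: str) -> bool:
        return key in self._data


class FileBackend:
    """Embedded file-based store: one subdirectory per key."""

    def __init__(self, root: str):
        self.root = root
        os.makedirs(root, exist_ok=True)

    def _dir(self, key: str) -> str:
        return os.path.join(self.root, hashlib.sha1(key.encode("utf-8")).hexdigest())

    def put_blob(self, key: str, name: str, data: bytes) -> None:
        d = self._dir(key)
        os.makedirs(d, exist_ok=True)
        tmp = os.path.join(d, name + ".tmp")
        try:
            with open(tmp, "wb") as fh:
                fh.write(data)
            os.replace(tmp, os.path.join(d, name))
        except OSError as e:
            raise StoreError(f"write failure for key {key!r}: {e}") from e

    def get_blob(self, key: str, name: str) -> bytes:
        try:
            with open(os.path.join(self._dir(key), name), "rb") as fh:
                return fh.read()
        except OSError as e:
            raise StoreError(f"read failure for key {key!r}/{name}: {e}") from e

    def delete_blob(self, key: str, name: str) -> None:
        try:
            os.remove(os.path.join(self._dir(key), name))
        except FileNotFoundError:
            pass

    def delete_key(self, key: str) -> None:
        shutil.rmtree(self._dir(key), ignore_errors=True)

    def list_keys(self) -> Iterator[str]:
        for entry in os.listdir(self.root):
            meta = os.path.join(self.root, entry, "meta.json")
            if os.path.exists(meta):
                with open(meta, "r", encoding="utf-8") as fh:
                    yield json.load(fh)["key"]

    def has_key(self, key: str) -> bool:
        return os.path.exists(os.path.join(self._dir(key), "meta.json"))


class ChunkStore:
    """Chunk-splitting key/value store with subrange retrieval."""

    def __init__(self, backend: Backend | str | None = None):
        if backend is None:
            backend = MemoryBackend()
        elif isinstance(backend, str):
            backend = FileBackend(backend)
        self.backend = backend
        self.chunk_reads = 0  # observable I/O counter (access contract)

    # ------------------------------------------------------------ write

    def put(self, key: str, data: bytes, chunk_size: int = DEFAULT_CHUNK_SIZE) -> ChunkRecord:
        """Store *data* under *key*, overwriting atomically."""
        if not key:
            raise ValueError("key must be non-empty")
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        n_chunks = (len(data) + chunk_size - 1) // chunk_size
        # write the new generation's chunks first, switch meta last, then
        # drop any stale tail chunks from a previous larger value
        old_n = 0
        if self.backend.has_key(key):
            old = self._meta(key)
            old_n = old.n_chunks
        for i in range(n_chunks):
            self.backend.put_blob(key, f"chunk-{i:08d}",
                                  data[i * chunk_size:(i + 1) * chunk_size])
        meta = ChunkRecord(key=key, total_length=len(data),
                           chunk_size=chunk_size, n_chunks=n_chunks)
        self.backend.put_blob(key, "meta.json", json.dumps({
            "key": key, "total_length": meta.total_length,
            "chunk_size": meta.chunk_size, "n_chunks": meta.n_chunks,
        }).encode("utf-8"))
        for i in range(n_chunks, old_n):
            self.backend.delete_blob(key, f"chunk-{i:08d}")
        return meta

    # ------------------------------------------------------------ read

    def _meta(self, key: str) -> ChunkRecord:
        if not self.backend.has_key(key):
            raise UnknownKeyError(f"unknown key {key!r}")
        m = json.loads(self.backend.get_blob(key, "meta.json").decode("utf-8"))
        return ChunkRecord(key=m["key"], total_length=m["total_length"],
                           chunk_size=m["chunk_size"], n_chunks=m["n_chunks"])

    def record(self, key: str) -> ChunkRecord:
        return self._meta(key)

    def exists(self, key: str) -> bool:
        return self.backend.has_key(key)

    def length(self, key: str) -> int:
        return self._meta(key).total_length

    def get(self, key: str, start: Optional[int] = None,
            stop: Optional[int] = None) -> bytes:
        """Return ``data[start:stop]`` reading only the overlapping chunks."""
        meta = self._meta(key)
        start = 0 if start is None else start
        stop = meta.total_length if stop is None else stop
        if start < 0 or start > stop:
            raise SubrangeError(f"invalid subrange [{start}, {stop})")
        if stop > meta.total_length:
            raise SubrangeError(
                f"stop {stop} beyond total_length {meta.total_length} of key {key!r}"
            )
        if start == stop:
            return b""
        first = start // meta.chunk_size
        last = (stop - 1) // meta.chunk_size
        parts = []
        for i in range(first, last + 1):
            parts.append(self.backend.get_blob(key, f"chunk-{i:08d}"))
            self.chunk_reads += 1
        blob = b"".join(parts)
        base = first * meta.chunk_size
        return blob[start - base: stop - base]

    # ------------------------------------------------------------ delete

    def delete(self, key: str) -> None:
        if not self.backend.has_key(key):
            log.warning("delete of unknown key %r: no-op", key)
            return
        self.backend.delete_key(key)

    def keys(self) -> list[str]:
        return sorted(self.backend.list_keys())
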