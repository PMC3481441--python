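"""Index sharding: many segments, one query entry point.

Documents are routed to shards by a stable hash of their doc_id, so any
shard count works for any input mix (explicit bank→shard pinning is
available through :func:`route_by_bank`).  A query fans out in two phases:

1. every shard reports its document count and per-term document
   frequencies for the query's scoring leaves (fuzzy/prefix leaves
   expanded against that shard's vocabulary);
2. every shard scores its matches with the summed *global* statistics and
   returns its top ``offset+limit``; the handler merges by
   (score desc, doc_id asc) and slices the page.

Because scoring uses global N/df everywhere, a distributed search is
hit-for-hit and score-for-score identical to running the same query on a
single merged index.  An unreachable shard fails the whole query loudly —
silently returning partial results would be silent data loss.

Shard handles may be local segment directories or ``http(s)://`` URLs of a
running service instance (any instance can coordinate).
"""

from __future__ import annotations

import hashlib
import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .errors import ShardUnreachableError
from .index import GlobalStats, Hit, Index, SearchResult
from .model import Schema
from .query import QueryNode, parse_query, print_query, normalize


def stable_hash(s: str) -> int:
    """Process-independent 64-bit hash (Python's builtin hash is salted)."""
    return int.from_bytes(hashlib.sha1(s.encode("utf-8")).digest()[:8], "big")


def route_document(doc_id: str, n_shards: int) -> int:
    """Deterministic shard index for a document: hash(doc_id) mod n_shards."""
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    return stable_hash(doc_id) % n_shards


def route_by_bank(bank_name: str, pinning: dict[str, int], n_shards: int) -> int:
    """Explicit bank→shard pinning (deployments that group banks per shard)."""
    shard = pinning.get(bank_name)
    if shard is None:
        return stable_hash(bank_name) % n_shards
    if not 0 <= shard < n_shards:
        raise ValueError(f"pinned shard {shard} out of range for {n_shards} shards")
    return shard


class LocalShard:
    """A shard backed by an in-process Index segment."""

    def __init__(self, index_or_path: Union[Index, str], schema: Schema | None = None):
        if isinstance(index_or_path, Index):
            self.index: Index | None = index_or_path
            self.name = index_or_path.path or "<memory>"
        else:
            self.name = index_or_path
            try:
                self.index = Index.open(index_or_path, schema=schema)
            except FileNotFoundError as e:
                self.index = None
                self._error = str(e)

    def _ix(self) -> Index:
        if self.index is None:
            raise ShardUnreachableError(f"shard {self.name!r}: {self._error}")
        return self.index

    def stats(self, ast: QueryNode) -> GlobalStats:
        return self._ix().collect_stats(ast, prenormalized=True)

    def search(self, ast: QueryNode, limit: Optional[int],
               stats: GlobalStats) -> SearchResult:
        return self._ix().search(ast, 0, limit, stats=stats, prenormalized=True)

    def get(self, doc_id: str):
        ix = self._ix()
        return ix.get(doc_id) if doc_id in ix else None


class RemoteShard:
    """A shard behind a running service instance, spoken to over HTTP."""

    def __init__(self, url: str, timeout: float = 10.0):
        self.name = self.url = url.rstrip("/")
        self.timeout = timeout

    def _call(self, route: str, params: dict) -> dict:
        q = urllib.parse.urlencode(params)
        try:
            with urllib.request.urlopen(f"{self.url}{route}?{q}",
                                        timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, ValueError) as e:
            raise ShardUnreachableError(f"shard {self.name!r} unreachable: {e}") from e

    def stats(self, ast: QueryNode) -> GlobalStats:
        body = self._call("/shard/stats", {"q": print_query(ast)})
        return GlobalStats(n=body["n"], df=dict(body["df"]))

    def search(self, ast: QueryNode, limit: Optional[int],
               stats: GlobalStats) -> SearchResult:
        body = self._call("/shard/search", {
            "q": print_query(ast),
            "rows": -1 if limit is None else limit,
            "stats": json.dumps({"n": stats.n, "df": stats.df}),
        })
        hits = [Hit(doc_id=h["id"], score=h["score"], fields=h["fields"],
                    content_type=h["content_type"]) for h in body["hits"]]
        return SearchResult(total=body["total"], hits=hits, offset=0, limit=limit)

    def get(self, doc_id: str):
        return None  # document fetch is served by the owning instance


Shard = Union[LocalShard, RemoteShard]


class ShardSet:
    """An ordered set of shards with one designated query handler.

    Any shard may coordinate; doc_ids must be unique across the whole set.
    """

    def __init__(self, shards: Sequence[Shard], schema: Schema | None = None,
                 handler: int = 0):
        if not shards:
            raise ValueError("ShardSet needs at least one shard")
        self.shards = list(shards)
        self.schema = schema or Schema()
        self.handler = handler

    @classmethod
    def from_paths(cls, paths: Sequence[str], schema: Schema | None = None) -> "ShardSet":
        shards: list[Shard] = []
        for p in paths:
            if p.startswith("http://") or p.startswith("https://"):
                shards.append(RemoteShard(p))
            else:
                shards.append(LocalShard(p, schema=schema))
        return cls(shards, schema=schema)

    def prepare(self, query: Union[str, QueryNode]) -> QueryNode:
        ast = parse_query(query) if isinstance(query, str) else query
        return normalize(ast, self.schema)

    def global_stats(self, ast: QueryNode) -> GlobalStats:
        n = 0
        df: dict[str, int] = {}
        for shard in self.shards:
            st = shard.stats(ast)
            n += st.n
            for key, val in st.df.items():
                df[key] = df.get(key, 0) + val
        return GlobalStats(n=n, df=df)

    def search(self, query: Union[str, QueryNode], offset: int = 0,
               limit: Optional[int] = 10) -> SearchResult:
        """Two-phase distributed search over all shards."""
        ast = self.prepare(query)
        stats = self.global_stats(ast)
        fetch = None if limit is None else offset + limit
        merged: list[Hit] = []
        total = 0
        for shard in self.shards:
            res = shard.search(ast, fetch, stats)
            total += res.total
            merged.extend(res.hits)
        merged.sort(key=lambda h: (-h.score, h.doc_id))
        page = merged[offset: None if limit is None else offset + limit]
        return SearchResult(total=total, hits=page, offset=offset, limit=limit)

    def get(self, doc_id: str):
        for shard in self.shards:
            doc = shard.get(doc_id)
            if doc is not None:
                return doc
        return None

    def local_indexes(self) -> list[Index]:
        return [s.index for s in self.shards
                if isinstance(s, LocalShard) and s.index is not None]
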