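"""Embedded inverted index.

One :class:`Index` is one *segment*: positional posting lists for text and
keyword fields, sorted (value, doc_id) arrays for numeric fields, a stored-
fields store, and the document/term statistics scoring needs.  Mutations
(add / update / delete) are staged and become visible atomically at
:meth:`Index.commit`, which also persists the segment to its directory
(write-temp + rename, so a crash between add and commit leaves the previous
committed state intact).

Scoring is a deliberately simple TF-IDF with no length normalization:

    score(d, q) = sum over positive scoring leaves t matching in field f of
                  (1 + ln tf(t, f, d)) * (1 + ln((N + 1) / (df(t, f) + 1)))

Range and negated leaves contribute 0; a pure-filter query (ranges only)
scores every match 1.0.  Ties are broken by ascending doc_id so paging is
deterministic.  ``N`` and ``df`` can be supplied externally, which is how
the shard manager makes distributed scores identical to a single index.
"""

from __future__ import annotations

import bisect
import json
import logging
import math
import os
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .analysis import fuzzy_expand, tokenize
from .errors import (
    FieldNotSearchableError,
    PartialUpdateError,
    QueryError,
    SchemaError,
    UnknownDocumentError,
)
from .model import Document, Schema, SourceLocation, Value
from .query import (
    Bool, Fuzzy, MatchAll, Phrase, Prefix, QueryNode, Range, Term,
    normalize, parse_query,
)

log = logging.getLogger("seqindex.index")

SEGMENT_FILE = "segment.json"
SEGMENT_FORMAT = "seqindex-segment"
SEGMENT_VERSION = 1

# positions of successive values of a multi-valued field are separated by
# this gap so phrases never match across value boundaries
POSITION_GAP = 100


def stats_key(field: str, termkey: str) -> str:
    return f"{field}\x1f{termkey}"


def phrase_key(tokens: Sequence[str]) -> str:
    return '"' + " ".join(tokens) + '"'


@dataclass
class Hit:
    doc_id: str
    score: float
    fields: dict[str, list[Value]]
    content_type: str


@dataclass
class SearchResult:
    """A page of ranked hits plus the paging-independent total."""

    total: int
    hits: list[Hit]
    offset: int
    limit: Optional[int]


@dataclass
class GlobalStats:
    """Corpus-wide statistics injected for distributed scoring."""

    n: int
    df: dict[str, int]


@dataclass
class _StoredDoc:
    fields: dict[str, list[Value]]
    content_type: str
    source: Optional[SourceLocation]
    indexed_only: list[str]  # fields indexed but not stored (blocks partial update)


class Index:
    """A single index segment with commit semantics.

    ``path=None`` gives an in-memory segment; with a directory path the
    committed state survives process restart (open with :meth:`Index.open`).
    """

    def __init__(self, path: str | None = None, schema: Schema | None = None):
        self.path = path
        self.schema = schema or Schema()
        self._docs: dict[str, _StoredDoc] = {}
        self._postings: dict[str, dict[str, dict[str, list[int]]]] = {}
        self._numeric: dict[str, list[tuple[float, str]]] = {}
        self._doc_terms: dict[str, list[tuple[str, str]]] = {}
        self._doc_numeric: dict[str, list[tuple[str, float]]] = {}
        self._pending: list[tuple] = []
        self._result_cache: dict = {}
        if path is not None:
            os.makedirs(path, exist_ok=True)
            if os.path.exists(os.path.join(path, SEGMENT_FILE)):
                self._load()

    # ------------------------------------------------------------ mutations

    def add_document(self, doc: Document) -> None:
        """Stage a document add; an existing doc_id is replaced at commit."""
        if not doc.doc_id:
            raise SchemaError("document without doc_id")
        self._pending.append(("add", doc))

    def update_document(self, doc_id: str, partial_fields: Mapping[str, Value | Sequence[Value]]) -> None:
        """Stage a partial update: named fields replaced, others preserved.

        Requires every field of the target document to be stored; a field
        that is indexed but unstored cannot be reconstructed for reindexing.
        """
        pending_adds = {d.doc_id for op, *rest in self._pending if op == "add"
                        for d in [rest[0]]}
        if doc_id not in self._docs and doc_id not in pending_adds:
            raise UnknownDocumentError(f"cannot update unknown doc_id {doc_id!r}")
        old = self._docs.get(doc_id)
        if old is not None and old.indexed_only:
            raise PartialUpdateError(
                f"document {doc_id!r} has indexed-only field(s) "
                f"{', '.join(sorted(old.indexed_only))}; partial update unsupported"
            )
        self._pending.append(("update", doc_id, dict(partial_fields)))

    def delete_document(self, doc_id: str) -> None:
        self._pending.append(("delete", doc_id))

    def commit(self) -> None:
        """Apply staged mutations atomically and persist the segment."""
        for op in self._pending:
            if op[0] == "add":
                self._apply_add(op[1])
            elif op[0] == "update":
                self._apply_update(op[1], op[2])
            elif op[0] == "delete":
                self._apply_delete(op[1])
        self._pending.clear()
        self._result_cache.clear()
        if self.path is not None:
            self._persist()

    def _apply_add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            self._apply_delete(doc.doc_id)
        stored: dict[str, list[Value]] = {}
        indexed_only: list[str] = []
        terms: list[tuple[str, str]] = []
        numerics: list[tuple[str, float]] = []
        for name, values in doc.fields.items():
            fs = self.schema.field(name)
            if fs.stored:
                stored[name] = list(values)
            if fs.indexed:
                if not fs.stored:
                    indexed_only.append(name)
                if fs.kind == "numeric":
                    for v in values:
                        try:
                            num = float(v)
                        except (TypeError, ValueError):
                            raise SchemaError(
                                f"non-numeric value {v!r} in numeric field {name!r}"
                            ) from None
                        numerics.append((name, num))
                else:
                    pos = 0
                    field_postings = self._postings.setdefault(name, {})
                    for v in values:
                        toks = ([str(v).lower()] if fs.kind == "keyword"
                                else tokenize(str(v)))
                        for t in toks:
                            field_postings.setdefault(t, {}).setdefault(
                                doc.doc_id, []).append(pos)
                            terms.append((name, t))
                            pos += 1
                        pos += POSITION_GAP
        for fname, num in numerics:
            bisect.insort(self._numeric.setdefault(fname, []), (num, doc.doc_id))
        self._docs[doc.doc_id] = _StoredDoc(
            fields=stored, content_type=doc.content_type,
            source=doc.source, indexed_only=indexed_only,
        )
        self._doc_terms[doc.doc_id] = terms
        self._doc_numeric[doc.doc_id] = numerics

    def _apply_update(self, doc_id: str, partial: dict) -> None:
        old = self._docs.get(doc_id)
        if old is None:
            raise UnknownDocumentError(f"cannot update unknown doc_id {doc_id!r}")
        if old.indexed_only:
            raise PartialUpdateError(
                f"document {doc_id!r} has indexed-only field(s); partial update unsupported"
            )
        fields = {k: list(v) for k, v in old.fields.items()}
        for k, v in partial.items():
            fields[k] = list(v) if isinstance(v, (list, tuple)) else [v]
        self._apply_add(Document(doc_id=doc_id, content_type=old.content_type,
                                 fields=fields, source=old.source))

    def _apply_delete(self, doc_id: str) -> None:
        if doc_id not in self._docs:
            log.warning("delete of unknown doc_id %r: no-op", doc_id)
            return
        for fname, term in set(self._doc_terms.pop(doc_id, [])):
            plist = self._postings.get(fname, {}).get(term)
            if plist is not None:
                plist.pop(doc_id, None)
                if not plist:
                    del self._postings[fname][term]
        for fname, num in self._doc_numeric.pop(doc_id, []):
            arr = self._numeric.get(fname, [])
            i = bisect.bisect_left(arr, (num, doc_id))
            if i < len(arr) and arr[i] == (num, doc_id):
                arr.pop(i)
        del self._docs[doc_id]

    # ------------------------------------------------------------ retrieval

    @property
    def doc_count(self) -> int:
        return len(self._docs)

    def get(self, doc_id: str) -> _StoredDoc:
        doc = self._docs.get(doc_id)
        if doc is None:
            raise UnknownDocumentError(f"unknown doc_id {doc_id!r}")
        return doc

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def doc_ids(self) -> list[str]:
        return sorted(self._docs)

    def df(self, field: str, term: str) -> int:
        return len(self._postings.get(field, {}).get(term, {}))

    def vocabulary(self, field: str) -> list[str]:
        return sorted(self._postings.get(field, {}))

    # ------------------------------------------------------------ search

    def prepare(self, query: Union[str, QueryNode]) -> QueryNode:
        ast = parse_query(query) if isinstance(query, str) else query
        return normalize(ast, self.schema)

    def search(
        self,
        query: Union[str, QueryNode],
        offset: int = 0,
        limit: Optional[int] = 10,
        *,
        stats: GlobalStats | None = None,
        prenormalized: bool = False,
    ) -> SearchResult:
        """Evaluate a query and return one ranked page.

        *offset*/*limit* page through the ranked list; ``limit=None``
        returns all matches.  *stats* overrides local N/df for distributed
        scoring.
        """
        if offset < 0 or (limit is not None and limit < 0):
            raise ValueError("offset and limit must be non-negative")
        ast = (query if prenormalized and not isinstance(query, str)
               else self.prepare(query))
        ev = _Evaluator(self, stats)
        matches = ev.eval(ast)
        scores = ev.score_all(matches)
        ranked = sorted(matches, key=lambda d: (-scores[d], d))
        page = ranked[offset: None if limit is None else offset + limit]
        hits = [Hit(doc_id=d, score=scores[d],
                    fields={k: list(v) for k, v in self._docs[d].fields.items()},
                    content_type=self._docs[d].content_type)
                for d in page]
        return SearchResult(total=len(ranked), hits=hits, offset=offset, limit=limit)

    def collect_stats(self, query: Union[str, QueryNode],
                      prenormalized: bool = False) -> GlobalStats:
        """Local (N, df) statistics for every scoring leaf of the query.

        Fuzzy and prefix leaves are expanded against the local vocabulary;
        phrase leaves report their local phrase document frequency.  The
        shard handler sums these across shards.
        """
        ast = (query if prenormalized and not isinstance(query, str)
               else self.prepare(query))
        ev = _Evaluator(self, None)
        ev.eval(ast)
        df: dict[str, int] = {}
        for contribs in ev.leaf_contribs:
            for (fname, termkey), doc_tf in contribs.items():
                key = stats_key(fname, termkey)
                # idempotent per key: two leaves naming the same term see
                # the same local df
                df[key] = (len(doc_tf) if termkey.startswith('"')
                           else self.df(fname, termkey))
        return GlobalStats(n=self.doc_count, df=df)

    def score_document(self, doc_id: str, query: Union[str, QueryNode],
                       stats: GlobalStats | None = None) -> float:
        """Score one matching document (closed-form entry point)."""
        ast = self.prepare(query) if isinstance(query, str) else normalize(query, self.schema)
        ev = _Evaluator(self, stats)
        matches = ev.eval(ast)
        if doc_id not in matches:
            raise QueryError(f"document {doc_id!r} does not match the query")
        return ev.score_all({doc_id})[doc_id]

    # ------------------------------------------------------------ persistence

    def _persist(self) -> None:
        state = {
            "format": SEGMENT_FORMAT,
            "version": SEGMENT_VERSION,
            "docs": {
                did: {
                    "fields": d.fields,
                    "content_type": d.content_type,
                    "source": (None if d.source is None else
                               {"path": d.source.path, "offset": d.source.offset,
                                "length": d.source.length}),
                    "indexed_only": d.indexed_only,
                }
                for did, d in self._docs.items()
            },
            "postings": self._postings,
            "numeric": {f: [[v, d] for v, d in arr]
                        for f, arr in self._numeric.items()},
            "doc_terms": {d: [[f, t] for f, t in v]
                          for d, v in self._doc_terms.items()},
            "doc_numeric": {d: [[f, n] for f, n in v]
                            for d, v in self._doc_numeric.items()},
        }
        tmp = os.path.join(self.path, SEGMENT_FILE + ".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(state, fh)
        os.replace(tmp, os.path.join(self.path, SEGMENT_FILE))

    def _load(self) -> None:
        with open(os.path.join(self.path, SEGMENT_FILE), "r", encoding="utf-8") as fh:
            state = json.load(fh)
        if state.get("format") != SEGMENT_FORMAT:
            raise SchemaError(f"{self.path}: not a seqindex segment")
        self._docs = {
            did: _StoredDoc(
                fields={k: list(v) for k, v in d["fields"].items()},
                content_type=d["content_type"],
                source=SourceLocation(**d["source"]) if d["source"] else None,
                indexed_only=list(d["indexed_only"]),
            )
            for did, d in state["docs"].items()
        }
        self._postings = state["postings"]
        self._numeric = {f: [(v, d) for v, d in arr]
                         for f, arr in state["numeric"].items()}
        self._doc_terms = {d: [(f, t) for f, t in v]
                           for d, v in state["doc_terms"].items()}
        self._doc_numeric = {d: [(f, n) for f, n in v]
                             for d, v in state["doc_numeric"].items()}

    @classmethod
    def open(cls, path: str, schema: Schema | None = None) -> "Index":
        if not os.path.exists(os.path.join(path, SEGMENT_FILE)):
            raise FileNotFoundError(f"no index segment at {path}")
        return cls(path=path, schema=schema)


class _Evaluator:
    """Evaluates a normalized AST against one segment.

    Collects per-leaf (field, termkey) -> {doc_id: tf} contribution maps as
    a side effect of evaluation; scoring replays them with either local or
    injected global statistics.
    """

    def __init__(self, index: Index, stats: GlobalStats | None):
        self.ix = index
        self.stats = stats
        self.leaf_contribs: list[dict[tuple[str, str], dict[str, int]]] = []
        self._has_scoring_leaf = False

    # -- helpers

    def _all_docs(self) -> set[str]:
        return set(self.ix._docs)

    def _target_fields(self, field: Optional[str], *, for_term: bool = True) -> list[str]:
        if field is not None:
            fs = self.ix.schema.field(field)
            if not fs.indexed:
                raise FieldNotSearchableError(
                    f"field {field!r} is stored but not indexed"
                )
            return [field]
        # full-text: every field holding postings (all indexed text/keyword)
        return sorted(self.ix._postings)

    def eval(self, node: QueryNode, negated: bool = False) -> set[str]:
        if isinstance(node, Term):
            return self._eval_term(node, negated)
        if isinstance(node, Phrase):
            return self._eval_phrase(node, negated)
        if isinstance(node, Prefix):
            return self._eval_expandable(node.field, negated,
                                         lambda vocab: [t for t in vocab
                                                        if t.startswith(node.text)])
        if isinstance(node, Fuzzy):
            return self._eval_expandable(node.field, negated,
                                         lambda vocab: fuzzy_expand(node.text, vocab,
                                                                    node.max_edits))
        if isinstance(node, Range):
            return self._eval_range(node)
        if isinstance(node, MatchAll):
            return self._all_docs()
        if isinstance(node, Bool):
            if node.op == "NOT":
                return self._all_docs() - self.eval(node.children[0], not negated)
            sets = [self.eval(c, negated) for c in node.children]
            if node.op == "AND":
                out = sets[0]
                for s in sets[1:]:
                    out = out & s
                return out
            out = set()
            for s in sets:
                out |= s
            return out
        raise QueryError(f"cannot evaluate node {node!r}")

    def _record(self, negated: bool,
                contribs: dict[tuple[str, str], dict[str, int]]) -> None:
        if not negated:
            self._has_scoring_leaf = True
            self.leaf_contribs.append(contribs)

    def _eval_term(self, node: Term, negated: bool) -> set[str]:
        contribs: dict[tuple[str, str], dict[str, int]] = {}
        matched: set[str] = set()
        for fname in self._target_fields(node.field):
            plist = self.ix._postings.get(fname, {}).get(node.text)
            if plist:
                contribs[(fname, node.text)] = {d: len(p) for d, p in plist.items()}
                matched |= set(plist)
            elif node.field is not None:
                contribs[(fname, node.text)] = {}
        self._record(negated, contribs)
        return matched

    def _eval_phrase(self, node: Phrase, negated: bool) -> set[str]:
        key = phrase_key(node.texts)
        contribs: dict[tuple[str, str], dict[str, int]] = {}
        matched: set[str] = set()
        for fname in self._target_fields(node.field):
            fp = self.ix._postings.get(fname, {})
            plists = [fp.get(t) for t in node.texts]
            if any(p is None for p in plists):
                continue
            docs = set(plists[0])
            for p in plists[1:]:
                docs &= set(p)
            doc_tf: dict[str, int] = {}
            for d in docs:
                possets = [set(p[d]) for p in plists]
                count = sum(1 for p0 in plists[0][d]
                            if all(p0 + i in possets[i] for i in range(1, len(possets))))
                if count:
                    doc_tf[d] = count
            if doc_tf:
                contribs[(fname, key)] = doc_tf
                matched |= set(doc_tf)
        self._record(negated, contribs)
        return matched

    def _eval_expandable(self, field: Optional[str], negated: bool, expand) -> set[str]:
        contribs: dict[tuple[str, str], dict[str, int]] = {}
        matched: set[str] = set()
        for fname in self._target_fields(field):
            vocab = self.ix._postings.get(fname, {})
            for t in expand(sorted(vocab)):
                plist = vocab[t]
                contribs[(fname, t)] = {d: len(p) for d, p in plist.items()}
                matched |= set(plist)
        self._record(negated, contribs)
        return matched

    def _eval_range(self, node: Range) -> set[str]:
        fs = self.ix.schema.field(node.field)
        if not fs.indexed:
            raise FieldNotSearchableError(f"field {node.field!r} is stored but not indexed")
        if fs.kind == "numeric":
            arr = self.ix._numeric.get(node.field, [])
            lo = 0 if node.low is None else bisect.bisect_left(arr, (float(node.low), ""))
            hi = (len(arr) if node.high is None
                  else bisect.bisect_right(arr, (float(node.high), "￿")))
            return {d for _, d in arr[lo:hi]}
        # lexicographic range over the field's vocabulary
        matched: set[str] = set()
        for t, plist in self.ix._postings.get(node.field, {}).items():
            if (node.low is None or t >= str(node.low)) and \
               (node.high is None or t <= str(node.high)):
                matched |= set(plist)
        return matched

    # -- scoring

    def _df_global(self, fname: str, termkey: str,
                   contribs: dict[str, int]) -> int:
        key = stats_key(fname, termkey)
        if self.stats is not None and key in self.stats.df:
            return self.stats.df[key]
        if termkey.startswith('"'):
            return len(contribs)
        return self.ix.df(fname, termkey)

    def score_all(self, matches: Iterable[str]) -> dict[str, float]:
        n = self.stats.n if self.stats is not None else self.ix.doc_count
        scores = {d: 0.0 for d in matches}
        if not self._has_scoring_leaf:
            return {d: 1.0 for d in scores}
        for contribs in self.leaf_contribs:
            for (fname, termkey), doc_tf in contribs.items():
                if not doc_tf:
                    continue
                df = self._df_global(fname, termkey, doc_tf)
                idf = 1.0 + math.log((n + 1) / (df + 1))
                for d, tf in doc_tf.items():
                    if d in scores:
                        scores[d] += (1.0 + math.log(tf)) * idf
        return scores
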