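"""REST-like query facade over a ShardSet and a ChunkStore.

Endpoints (all GET unless noted):

- ``/search?q=&start=0&rows=10&format=json|csv`` — ranked, paged results;
  parameter names mirror the Solr dialect (q/start/rows).  CSV flattens
  multi-valued fields with ``;`` — the result-export mechanism.
- ``/document/<id>`` — every stored key/value of one document, its
  content type, its source location, and links to any stored payloads.
- ``/storage/<key>?start=&stop=`` — raw payload bytes, with optional
  0-based stop-exclusive subrange.
- ``/region?seqid=&from=&to=&type=`` — GFF3 body of overlapping features.
- ``/shard/stats`` and ``/shard/search`` — the distributed-search wire
  protocol, so any service instance can be a remote shard of another.
- ``POST /ingest`` — online indexing: a JSON list of documents is added
  and committed with no restart.

The app is a plain WSGI callable; :func:`serve` wraps it in the stdlib
server.  No authentication, by design.
"""

from __future__ import annotations

import io
import json
import urllib.parse
from typing import Callable, Iterable, Optional

from .chunks import ChunkStore
from .errors import (
    QueryError,
    QuerySyntaxError,
    SeqIndexError,
    SubrangeError,
    UnknownKeyError,
)
from .index import GlobalStats
from .model import Document, default_registry
from .region import Region, export_region_gff, features_in_region, sequence_of_region
from .shards import ShardSet, route_document


class Service:
    """Ties the shard set, chunk store and content-type registry together."""

    def __init__(self, shardset: ShardSet, store: ChunkStore | None = None,
                 content_types=None):
        self.shards = shardset
        self.store = store or ChunkStore()
        self.content_types = content_types or default_registry()

    # ------------------------------------------------------------ handlers

    def search_json(self, q: str, start: int, rows: int) -> dict:
        result = self.shards.search(q, start, rows)
        return {
            "total": result.total,
            "offset": result.offset,
            "rows": rows,
            "hits": [
                {"id": h.doc_id, "score": h.score,
                 "content_type": h.content_type, "fields": h.fields}
                for h in result.hits
            ],
        }

    def search_csv(self, q: str, start: int, rows: int) -> str:
        body = self.search_json(q, start, rows)
        names = sorted({k for h in body["hits"] for k in h["fields"]})
        out = io.StringIO()
        out.write(",".join(["id", "score", "content_type"] + names) + "\r\n")
        for h in body["hits"]:
            row = [h["id"], f"{h['score']:.6f}", h["content_type"]]
            for nm in names:
                row.append(";".join(str(v) for v in h["fields"].get(nm, [])))
            out.write(",".join(_csv_quote(c) for c in row) + "\r\n")
        return out.getvalue()

    def document_json(self, doc_id: str) -> Optional[dict]:
        doc = self.shards.get(doc_id)
        if doc is None:
            return None
        body: dict = {
            "id": doc_id,
            "content_type": doc.content_type,
            "fields": doc.fields,
        }
        if doc.source is not None:
            body["source"] = {"path": doc.source.path,
                             "offset": doc.source.offset,
                             "length": doc.source.length}
        links = [f"/storage/{urllib.parse.quote(k, safe='')}"
                 for k in (doc_id, f"{doc_id}:translation")
                 if self.store.exists(k)]
        if links:
            body["links"] = links
        return body

    def region_gff(self, seqid: str, start: int, end: int,
                   type_filter: Optional[str]) -> str:
        region = Region(seqid=seqid, start=start, end=end)
        feats = features_in_region(self.shards, region, type_filter)
        return export_region_gff(feats, region)

    def ingest(self, documents: Iterable[dict]) -> dict:
        indexes = self.shards.local_indexes()
        if not indexes:
            raise SeqIndexError("no local shards accept online ingest")
        added = 0
        for d in documents:
            doc = Document.from_json(d)
            self.content_types.lookup(doc.content_type)
            indexes[route_document(doc.doc_id, len(indexes))].add_document(doc)
            added += 1
        for ix in indexes:
            ix.commit()
        return {"added": added}

    # ------------------------------------------------------------ WSGI

    def wsgi_app(self, environ, start_response):
        try:
            status, ctype, body = self._route(environ)
        except (QuerySyntaxError, QueryError, SubrangeError, ValueError) as e:
            status, ctype, body = 400, "application/json", json.dumps(
                {"error": str(e)}).encode("utf-8")
        except (UnknownKeyError,) as e:
            status, ctype, body = 404, "application/json", json.dumps(
                {"error": str(e)}).encode("utf-8")
        except SeqIndexError as e:
            status, ctype, body = 500, "application/json", json.dumps(
                {"error": str(e)}).encode("utf-8")
        reasons = {200: "OK", 400: "Bad Request", 404: "Not Found",
                   500: "Internal Server Error"}
        start_response(f"{status} {reasons[status]}",
                       [("Content-Type", ctype),
                        ("Content-Length", str(len(body)))])
        return [body]

    __call__ = wsgi_app

    def _route(self, environ) -> tuple[int, str, bytes]:
        path = environ.get("PATH_INFO", "/")
        qs = urllib.parse.parse_qs(environ.get("QUERY_STRING", ""))

        def p(name: str, default=None):
            return qs.get(name, [default])[0]

        if path == "/search":
            q = p("q")
            if not q:
                raise QueryError("missing parameter 'q'")
            start, rows = int(p("start", "0")), int(p("rows", "10"))
            if p("format", "json") == "csv":
                return 200, "text/csv", self.search_csv(q, start, rows).encode("utf-8")
            return 200, "application/json", json.dumps(
                self.search_json(q, start, rows)).encode("utf-8")

        if path.startswith("/document/"):
            doc_id = urllib.parse.unquote(path[len("/document/"):])
            body = self.document_json(doc_id)
            if body is None:
                return 404, "application/json", json.dumps(
                    {"error": f"unknown document {doc_id!r}"}).encode("utf-8")
            return 200, "application/json", json.dumps(body).encode("utf-8")

        if path.startswith("/storage/"):
            key = urllib.parse.unquote(path[len("/storage/"):])
            start = p("start")
            stop = p("stop")
            data = self.store.get(key,
                                  None if start is None else int(start),
                                  None if stop is None else int(stop))
            return 200, "application/octet-stream", data

        if path == "/region":
            seqid = p("seqid")
            if not seqid:
                raise QueryError("missing parameter 'seqid'")
            start = int(p("from", "1"))
            end = int(p("to", "1"))
            gff = self.region_gff(seqid, start, end, p("type"))
            return 200, "text/plain", gff.encode("utf-8")

        if path == "/sequence":
            seqid = p("seqid")
            if not seqid:
                raise QueryError("missing parameter 'seqid'")
            region = Region(seqid=seqid, start=int(p("from", "1")),
                            end=int(p("to", "1")))
            seq = sequence_of_region(self.store, region)
            return 200, "text/plain", seq.encode("ascii")

        if path == "/shard/stats":
            ast = self.shards.prepare(p("q") or "")
            indexes = self.shards.local_indexes()
            n, df = 0, {}
            for ix in indexes:
                st = ix.collect_stats(ast, prenormalized=True)
                n += st.n
                for k, v in st.df.items():
                    df[k] = df.get(k, 0) + v
            return 200, "application/json", json.dumps(
                {"n": n, "df": df}).encode("utf-8")

        if path == "/shard/search":
            ast = self.shards.prepare(p("q") or "")
            rows = int(p("rows", "10"))
            stats_raw = json.loads(p("stats") or "{}")
            stats = GlobalStats(n=stats_raw.get("n", 0),
                                df=dict(stats_raw.get("df", {})))
            merged_hits = []
            total = 0
            for ix in self.shards.local_indexes():
                res = ix.search(ast, 0, None if rows < 0 else rows,
                                stats=stats, prenormalized=True)
                total += res.total
                merged_hits.extend(res.hits)
            merged_hits.sort(key=lambda h: (-h.score, h.doc_id))
            if rows >= 0:
                merged_hits = merged_hits[:rows]
            return 200, "application/json", json.dumps({
                "total": total,
                "hits": [{"id": h.doc_id, "score": h.score,
                          "content_type": h.content_type, "fields": h.fields}
                         for h in merged_hits],
            }).encode("utf-8")

        if path == "/ingest" and environ.get("REQUEST_METHOD") == "POST":
            length = int(environ.get("CONTENT_LENGTH") or 0)
            payload = environ["wsgi.input"].read(length)
            docs = json.loads(payload.decode("utf-8"))
            return 200, "application/json", json.dumps(
                self.ingest(docs)).encode("utf-8")

        return 404, "application/json", json.dumps(
            {"error": f"no route {path!r}"}).encode("utf-8")


def _csv_quote(s: str) -> str:
    if any(c in s for c in ',"\n'):
        return '"' + s.replace('"', '""') + '"'
    return s


def serve(service: Service, host: str = "127.0.0.1", port: int = 8080):
    """Run the service in the stdlib WSGI server (blocking)."""
    from wsgiref.simple_server import make_server, WSGIRequestHandler

    class QuietHandler(WSGIRequestHandler):
        def log_message(self, *args):  # keep test output clean
            pass

    httpd = make_server(host, port, service.wsgi_app, handler_class=QuietHandler)
    return httpd
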