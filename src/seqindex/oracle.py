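"""Reference query evaluation by brute-force linear scan.

`linear_scan` re-evaluates a query AST directly against raw documents,
one by one, with no posting lists, no numeric trees and no vocabulary
structures — an independent code path used to cross-check the inverted
index (the index and this scan must agree set-exactly on every query).

`random_queries` draws a mixed workload (terms, phrases, ranges, fuzzy,
prefix, boolean combinations, with and without fields) from a corpus
vocabulary, for the oracle-equivalence and sharding-transparency suites.
"""

from __future__ import annotations

import random
from typing import Iterable, Sequence

from .analysis import damerau_levenshtein, tokenize
from .model import Document, Schema
from .query import (
    Bool, Fuzzy, MatchAll, Phrase, Prefix, QueryNode, Range, Term,
)

POSITION_GAP = 100  # must mirror the index's multi-value position gap


def _field_tokens(doc: Document, schema: Schema, name: str) -> list[str]:
    fs = schema.field(name)
    values = doc.fields.get(name, [])
    if fs.kind == "keyword":
        return [str(v).lower() for v in values]
    toks: list[str] = []
    for v in values:
        toks.extend(tokenize(str(v)))
    return toks


def _field_positions(doc: Document, schema: Schema, name: str) -> dict[str, list[int]]:
    fs = schema.field(name)
    out: dict[str, list[int]] = {}
    pos = 0
    for v in doc.fields.get(name, []):
        toks = ([str(v).lower()] if fs.kind == "keyword" else tokenize(str(v)))
        for t in toks:
            out.setdefault(t, []).append(pos)
            pos += 1
        pos += POSITION_GAP
    return out


def _text_fields(doc: Document, schema: Schema) -> list[str]:
    return [name for name in doc.fields
            if schema.field(name).indexed and schema.field(name).kind != "numeric"]


def matches(doc: Document, node: QueryNode, schema: Schema) -> bool:
    """Does *doc* match the normalized AST *node*? (direct re-evaluation)"""
    if isinstance(node, Term):
        fields = [node.field] if node.field else _text_fields(doc, schema)
        return any(node.text in _field_tokens(doc, schema, f) for f in fields)
    if isinstance(node, Phrase):
        fields = [node.field] if node.field else _text_fields(doc, schema)
        for f in fields:
            pos = _field_positions(doc, schema, f)
            plists = [pos.get(t) for t in node.texts]
            if any(p is None for p in plists):
                continue
            sets = [set(p) for p in plists]
            if any(all(p0 + i in sets[i] for i in range(1, len(sets)))
                   for p0 in plists[0]):
                return True
        return False
    if isinstance(node, Prefix):
        fields = [node.field] if node.field else _text_fields(doc, schema)
        return any(t.startswith(node.text)
                   for f in fields for t in _field_tokens(doc, schema, f))
    if isinstance(node, Fuzzy):
        fields = [node.field] if node.field else _text_fields(doc, schema)
        return any(
            damerau_levenshtein(node.text, t, cap=node.max_edits) <= node.max_edits
            for f in fields for t in _field_tokens(doc, schema, f))
    if isinstance(node, Range):
        fs = schema.field(node.field)
        if fs.kind == "numeric":
            for v in doc.fields.get(node.field, []):
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    continue
                if ((node.low is None or x >= float(node.low)) and
                        (node.high is None or x <= float(node.high))):
                    return True
            return False
        for t in _field_tokens(doc, schema, node.field):
            if ((node.low is None or t >= str(node.low)) and
                    (node.high is None or t <= str(node.high))):
                return True
        return False
    if isinstance(node, MatchAll):
        return True
    if isinstance(node, Bool):
        if node.op == "NOT":
            return not matches(doc, node.children[0], schema)
        if node.op == "AND":
            return all(matches(doc, c, schema) for c in node.children)
        return any(matches(doc, c, schema) for c in node.children)
    raise TypeError(f"not a query node: {node!r}")


def linear_scan(docs: Iterable[Document], node: QueryNode, schema: Schema) -> set[str]:
    """doc_ids of all documents matching the normalized AST."""
    return {d.doc_id for d in docs if matches(d, node, schema)}


# ----------------------------------------------------------- query workload

def _perturb(rng: random.Random, word: str) -> str:
    """One random edit (sub/del/ins/transpose) to exercise fuzzy matching."""
    if len(word) < 3:
        return word + rng.choice("abc")
    i = rng.randrange(len(word) - 1)
    op = rng.randrange(4)
    if op == 0:
        return word[:i] + rng.choice("abcdefgh") + word[i + 1:]
    if op == 1:
        return word[:i] + word[i + 1:]
    if op == 2:
        return word[:i] + rng.choice("abcdefgh") + word[i:]
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def random_queries(
    n: int,
    seed: int,
    text_vocab: dict[str, Sequence[str]],
    numeric_fields: dict[str, tuple[float, float]],
) -> list[str]:
    """Generate *n* query strings mixing every supported construct.

    *text_vocab* maps text field names to sample tokens; *numeric_fields*
    maps numeric field names to (lo, hi) value ranges.
    """
    rng = random.Random(seed)
    tfields = sorted(text_vocab)
    queries: list[str] = []

    def term(fielded: bool | None = None) -> str:
        f = rng.choice(tfields)
        w = rng.choice(list(text_vocab[f]))
        if fielded is None:
            fielded = rng.random() < 0.5
        return f"{f}:{w}" if fielded else w

    def rng_clause() -> str:
        f = rng.choice(sorted(numeric_fields))
        lo, hi = numeric_fields[f]
        a = rng.randint(int(lo), int(hi))
        b = rng.randint(a, int(hi))
        style = rng.randrange(3)
        if style == 0:
            return f"{f}:[{a} TO {b}]"
        if style == 1:
            return f"{f}:[* TO {b}]"
        return f"{f}:[{a} TO *]"

    def fuzzy_clause() -> str:
        f = rng.choice(tfields)
        w = _perturb(rng, rng.choice(list(text_vocab[f])))
        n_edits = rng.choice((1, 2))
        base = f"{f}:{w}" if rng.random() < 0.5 else w
        return f"{base}~{n_edits}"

    def prefix_clause() -> str:
        f = rng.choice(tfields)
        w = rng.choice(list(text_vocab[f]))
        cut = max(2, len(w) - rng.randint(1, max(1, len(w) - 2)))
        base = w[:cut]
        return (f"{f}:{base}*" if rng.random() < 0.5 else f"{base}*")

    simple = [term, rng_clause, fuzzy_clause, prefix_clause]
    for _ in range(n):
        kind = rng.randrange(6)
        if kind == 0:
            q = rng.choice(simple)()
        elif kind == 1:
            q = f"{rng.choice(simple)()} AND {rng.choice(simple)()}"
        elif kind == 2:
            q = f"{rng.choice(simple)()} OR {rng.choice(simple)()}"
        elif kind == 3:
            q = f"{rng.choice(simple)()} NOT {rng.choice(simple)()}"
        elif kind == 4:
            q = (f"({rng.choice(simple)()} OR {rng.choice(simple)()}) "
                 f"AND {rng.choice(simple)()}")
        else:
            q = f"{term()} {rng_clause()}"  # implicit AND
        queries.append(q)
    return queries
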