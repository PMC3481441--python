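"""Lucene-style query language: AST, parser, normalizer, printer.

Supported grammar (the subset the search engine promises):

- ``field:term`` and bare ``term`` (bare clauses search all indexed text
  fields — full-text);
- ``field:"a phrase"`` / ``"a phrase"``;
- ``field:[x TO y]`` ranged queries, bounds inclusive, ``*`` for an open
  bound; a range always names a field;
- ``term~`` / ``term~1`` / ``term~2`` fuzzy matching (Damerau–Levenshtein
  edit distance, default 2);
- ``prefix*`` starts-with matching;
- ``AND`` / ``OR`` / ``NOT`` (uppercase) with parentheses; two adjacent
  clauses with no operator combine with AND; precedence NOT > AND > OR.

Boosts (``^``), regexes and proximity phrases are not part of the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

from .errors import QueryError, QuerySyntaxError
from .model import Schema

Bound = Union[str, int, float, None]


@dataclass(frozen=True)
class Term:
    field: Optional[str]
    text: str


@dataclass(frozen=True)
class Phrase:
    field: Optional[str]
    texts: tuple[str, ...]


@dataclass(frozen=True)
class Range:
    field: str
    low: Bound
    high: Bound


@dataclass(frozen=True)
class Fuzzy:
    field: Optional[str]
    text: str
    max_edits: int = 2

    def __post_init__(self) -> None:
        if self.max_edits not in (1, 2):
            raise QueryError(f"fuzzy max_edits must be 1 or 2, got {self.max_edits}")


@dataclass(frozen=True)
class Prefix:
    field: Optional[str]
    text: str


@dataclass(frozen=True)
class MatchAll:
    pass


@dataclass(frozen=True)
class Bool:
    op: str  # AND | OR | NOT
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR", "NOT"):
            raise QueryError(f"bad boolean op {self.op!r}")
        if self.op == "NOT" and len(self.children) != 1:
            raise QueryError("NOT is unary")


QueryNode = Union[Term, Phrase, Range, Fuzzy, Prefix, MatchAll, Bool]


# ---------------------------------------------------------------- lexer

_SPECIAL = set('():"[]~ \t')


class _Lexer:
    def __init__(self, q: str):
        self.q = q
        self.i = 0

    def error(self, msg: str, col: int | None = None) -> QuerySyntaxError:
        return QuerySyntaxError(msg, self.i if col is None else col)

    def skip_ws(self) -> None:
        while self.i < len(self.q) and self.q[self.i] in " \t\r\n":
            self.i += 1

    def peek(self) -> str:
        return self.q[self.i] if self.i < len(self.q) else ""

    def eof(self) -> bool:
        self.skip_ws()
        return self.i >= len(self.q)

    def read_word(self) -> str:
        start = self.i
        while self.i < len(self.q) and self.q[self.i] not in _SPECIAL:
            self.i += 1
        if self.i == start:
            found = (repr(self.q[self.i]) if self.i < len(self.q)
                     else "end of input")
            raise self.error(f"unexpected {found}")
        return self.q[start:self.i]

    def read_quoted(self) -> str:
        start = self.i
        assert self.q[self.i] == '"'
        self.i += 1
        begin = self.i
        while self.i < len(self.q) and self.q[self.i] != '"':
            self.i += 1
        if self.i >= len(self.q):
            raise self.error("unbalanced quote", start)
        text = self.q[begin:self.i]
        self.i += 1
        return text


# ---------------------------------------------------------------- parser

class _Parser:
    def __init__(self, q: str):
        self.lx = _Lexer(q)

    def parse(self) -> QueryNode:
        node = self.parse_or()
        if not self.lx.eof():
            raise self.lx.error("trailing input")
        return node

    def parse_or(self) -> QueryNode:
        children = [self.parse_and()]
        while True:
            save = self.lx.i
            if self._keyword("OR"):
                children.append(self.parse_and())
            else:
                self.lx.i = save
                break
        return children[0] if len(children) == 1 else Bool("OR", tuple(children))

    def parse_and(self) -> QueryNode:
        children = [self.parse_not()]
        while True:
            save = self.lx.i
            if self._keyword("AND"):
                children.append(self.parse_not())
                continue
            self.lx.i = save
            # implicit AND: another clause starts here (but not OR / ')')
            if self._lookahead_clause():
                children.append(self.parse_not())
                continue
            break
        return children[0] if len(children) == 1 else Bool("AND", tuple(children))

    def parse_not(self) -> QueryNode:
        save = self.lx.i
        if self._keyword("NOT"):
            return Bool("NOT", (self.parse_not(),))
        self.lx.i = save
        return self.parse_primary()

    def parse_primary(self) -> QueryNode:
        self.lx.skip_ws()
        if self.lx.peek() == "(":
            self.lx.i += 1
            node = self.parse_or()
            self.lx.skip_ws()
            if self.lx.peek() != ")":
                raise self.lx.error("unbalanced parenthesis")
            self.lx.i += 1
            return node
        return self.parse_clause()

    def _keyword(self, kw: str) -> bool:
        self.lx.skip_ws()
        if self.lx.q.startswith(kw, self.lx.i):
            end = self.lx.i + len(kw)
            if end >= len(self.lx.q) or self.lx.q[end] in " \t()\"":
                self.lx.i = end
                return True
        return False

    def _lookahead_clause(self) -> bool:
        self.lx.skip_ws()
        c = self.lx.peek()
        if not c or c == ")":
            return False
        save = self.lx.i
        if self._keyword("OR") or self._keyword("AND"):
            self.lx.i = save
            return False
        self.lx.i = save
        return True

    def parse_clause(self) -> QueryNode:
        self.lx.skip_ws()
        field: Optional[str] = None
        start = self.lx.i
        if self.lx.peek() == '"':
            texts = self.lx.read_quoted()
            return Phrase(None, (texts,))
        word = self.lx.read_word()
        if self.lx.peek() == ":":
            field = word
            self.lx.i += 1
            return self._parse_value(field)
        return self._finish_term(None, word, start)

    def _parse_value(self, field: str) -> QueryNode:
        c = self.lx.peek()
        if c == '"':
            return Phrase(field, (self.lx.read_quoted(),))
        if c == "[":
            return self._parse_range(field)
        if not c or c in _SPECIAL:
            raise self.lx.error(f"missing value for field {field!r}")
        start = self.lx.i
        word = self.lx.read_word()
        # values like Dbxref:GO:0005634 keep their inner colons
        while self.lx.peek() == ":":
            self.lx.i += 1
            word += ":" + (self.lx.read_word() if self.lx.peek() not in _SPECIAL and self.lx.peek() else "")
        return self._finish_term(field, word, start)

    def _parse_range(self, field: str) -> Range:
        open_col = self.lx.i
        self.lx.i += 1  # '['
        self.lx.skip_ws()
        low = self.lx.read_word()
        self.lx.skip_ws()
        if not self.lx.q.startswith("TO", self.lx.i):
            raise self.lx.error("range requires 'TO'")
        self.lx.i += 2
        self.lx.skip_ws()
        high = self.lx.read_word()
        self.lx.skip_ws()
        if self.lx.peek() != "]":
            raise self.lx.error("unclosed range bracket", open_col)
        self.lx.i += 1
        return Range(field,
                     None if low == "*" else low,
                     None if high == "*" else high)

    def _finish_term(self, field: Optional[str], word: str, start: int) -> QueryNode:
        if self.lx.peek() == "~":
            self.lx.i += 1
            edits = 2
            if self.lx.peek().isdigit():
                edits = int(self.lx.read_word())
            if edits not in (1, 2):
                raise self.lx.error("fuzzy edit distance must be 1 or 2", start)
            return Fuzzy(field, word, edits)
        if word.endswith("*") and len(word) > 1 and "*" not in word[:-1]:
            return Prefix(field, word[:-1])
        if word == "*":
            return MatchAll()
        return Term(field, word)


def parse_query(q: str) -> QueryNode:
    """Parse a query string into an AST; syntax errors report the column."""
    if not q or not q.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(q).parse()


# ------------------------------------------------------------- normalize

def _cast_bound(value: Bound, field: str) -> Bound:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise QueryError(
            f"non-numeric bound {value!r} on numeric field {field!r}"
        ) from None
    return int(f) if f == int(f) else f


def normalize(ast: QueryNode, schema: Schema) -> QueryNode:
    """Lower terms per the analyzer, cast range bounds, rewrite pure NOT.

    A multi-token term against a text field becomes an AND of its tokens;
    numeric range bounds are cast to numbers (error if impossible); a query
    that is pure NOT is rewritten to (match-all AND NOT x) so it has a
    positive component to evaluate.
    """
    from .analysis import tokenize  # local import to avoid a cycle

    def norm(node: QueryNode) -> QueryNode:
        if isinstance(node, Term):
            fs = schema.field(node.field) if node.field else None
            if fs is not None and fs.kind == "numeric":
                return Range(node.field, _cast_bound(node.text, node.field),
                             _cast_bound(node.text, node.field))
            if fs is not None and fs.kind == "keyword":
                return Term(node.field, node.text.lower())
            toks = tokenize(node.text)
            if not toks:
                return Bool("AND", (MatchAll(), Bool("NOT", (MatchAll(),))))
            if len(toks) == 1:
                return Term(node.field, toks[0])
            return Bool("AND", tuple(Term(node.field, t) for t in toks))
        if isinstance(node, Phrase):
            toks: list[str] = []
            for t in node.texts:
                toks.extend(tokenize(t))
            if not toks:
                return Bool("AND", (MatchAll(), Bool("NOT", (MatchAll(),))))
            return Phrase(node.field, tuple(toks))
        if isinstance(node, Range):
            fs = schema.field(node.field)
            if fs.kind == "numeric":
                return Range(node.field, _cast_bound(node.low, node.field),
                             _cast_bound(node.high, node.field))
            low = node.low.lower() if isinstance(node.low, str) else node.low
            high = node.high.lower() if isinstance(node.high, str) else node.high
            return Range(node.field, low, high)
        if isinstance(node, Fuzzy):
            return Fuzzy(node.field, node.text.lower(), node.max_edits)
        if isinstance(node, Prefix):
            return Prefix(node.field, node.text.lower())
        if isinstance(node, Bool):
            return Bool(node.op, tuple(norm(c) for c in node.children))
        return node

    out = norm(ast)
    if _is_pure_negative(out):
        out = Bool("AND", (MatchAll(), out))
    return out


def _is_pure_negative(node: QueryNode) -> bool:
    if isinstance(node, Bool):
        if node.op == "NOT":
            return True
        return all(_is_pure_negative(c) for c in node.children)
    return False


# ---------------------------------------------------------------- printer

def print_query(node: QueryNode) -> str:
    """Canonical string form; parse(print_query(ast)) round-trips."""
    def p(n: QueryNode) -> str:
        if isinstance(n, Term):
            return f"{n.field}:{n.text}" if n.field else n.text
        if isinstance(n, Phrase):
            body = f'"{" ".join(n.texts)}"'
            return f"{n.field}:{body}" if n.field else body
        if isinstance(n, Range):
            lo = "*" if n.low is None else str(n.low)
            hi = "*" if n.high is None else str(n.high)
            return f"{n.field}:[{lo} TO {hi}]"
        if isinstance(n, Fuzzy):
            base = f"{n.field}:{n.text}" if n.field else n.text
            return f"{base}~{n.max_edits}"
        if isinstance(n, Prefix):
            base = f"{n.field}:{n.text}" if n.field else n.text
            return f"{base}*"
        if isinstance(n, MatchAll):
            return "*"
        if isinstance(n, Bool):
            if n.op == "NOT":
                return f"(NOT {p(n.children[0])})"
            sep = f" {n.op} "
            return "(" + sep.join(p(c) for c in n.children) + ")"
        raise TypeError(f"not a query node: {n!r}")

    return p(node)
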