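"""Section-scoped positional inverted index and Boolean query engine.

Tokens are posted under every category field of the section they occur in
(a section tagged {RESULTS, DISCUSSION} is retrievable under both), plus
pseudo-fields TITLE and ABSTRACT.  The query dialect supports uppercase
AND/OR/NOT with parentheses (precedence NOT > AND > OR, adjacency is
implicit AND), ``FIELD:token`` and ``FIELD:"quoted phrase"`` scoping, and
``PUB_YEAR:<year>`` equality filters.

Unfielded terms search every field but drop articles whose only hits lie
in the References field — matching the default behaviour of excluding
articles that merely cite the query term.  An explicit ``REF:`` clause
bypasses the exclusion, so ``mTOR OR REF:mTOR`` also retrieves articles
where the term occurs only in the reference list.  The exclusion applies
per atomic unfielded clause, not to the whole Boolean result.

Results are unranked document-id sets; relevance ordering is out of scope.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .jats_io import ArticleDocument, iter_sections
from .section_tagger import CATEGORY_CODES, TaggedArticle

__all__ = [
    "FIELD_CODES",
    "FieldedIndex",
    "IndexingError",
    "QuerySyntaxError",
    "QueryFieldError",
    "Term",
    "Phrase",
    "Bool",
    "YearEq",
    "QueryNode",
    "tokenize",
    "build_index",
    "parse_query",
    "execute",
    "search",
]

#: searchable fields: the 17 category codes plus title/abstract pseudo-fields
FIELD_CODES: tuple[str, ...] = CATEGORY_CODES + ("TITLE", "ABSTRACT")

# position gap between sections: phrases never match across a section
# boundary because positions are only ever consecutive within one section
_SECTION_GAP = 100

_INDEX_FORMAT_VERSION = 1


class IndexingError(ValueError):
    """Invalid input while building the index (e.g. duplicate doc id)."""


class QuerySyntaxError(ValueError):
    """The query string violates the grammar."""


class QueryFieldError(ValueError):
    """The query names a field the index does not expose."""


_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Case-fold and split on runs of non-alphanumerics (hyphens split)."""
    return _TOKEN_RE.findall(text.casefold())


# ---------------------------------------------------------------------------
# Index

class FieldedIndex:
    """Positional postings keyed by (term, field), with per-doc metadata.

    Positions are document-global token offsets shared across fields, so a
    multi-category section posts identical positions under each of its
    fields, and phrase matching (consecutive positions within one field)
    can never bridge two sections.
    """

    def __init__(self) -> None:
        # term -> field -> doc_id -> sorted positions
        self.postings: dict[str, dict[str, dict[str, list[int]]]] = {}
        # doc_id -> {"pub_year": int|None, "field_tokens": {field: count}}
        self.doc_meta: dict[str, dict] = {}

    # -- construction -------------------------------------------------------

    def add_article(self, doc: ArticleDocument, tagged: TaggedArticle) -> None:
        doc_id = doc.article_id
        if doc_id in self.doc_meta:
            raise IndexingError(f"duplicate document id {doc_id!r}")
        field_tokens: dict[str, int] = {}
        self.doc_meta[doc_id] = {
            "pub_year": doc.pub_year,
            "field_tokens": field_tokens,
        }
        cats_by_path = {s.path: s.categories for s in tagged.sections}

        offset = 0

        def post(tokens: list[str], fields: Iterable[str]) -> None:
            nonlocal offset
            fields = list(fields)
            for i, token in enumerate(tokens):
                for f in fields:
                    self.postings.setdefault(token, {}).setdefault(
                        f, {}
                    ).setdefault(doc_id, []).append(offset + i)
            for f in fields:
                field_tokens[f] = field_tokens.get(f, 0) + len(tokens)
            offset += len(tokens) + _SECTION_GAP

        post(tokenize(doc.title), ["TITLE"])
        if doc.abstract:
            post(tokenize(doc.abstract), ["ABSTRACT"])
        for path, node in iter_sections(doc):
            fields = sorted(cats_by_path.get(path, frozenset()))
            if not fields:
                continue
            text = " ".join([node.heading_raw, *node.paragraphs])
            tokens = tokenize(text)
            if tokens:
                post(tokens, fields)

    # -- lookups -------------------------------------------------------------

    @property
    def all_docs(self) -> set[str]:
        return set(self.doc_meta)

    def _field_postings(self, term: str, fld: str) -> dict[str, list[int]]:
        return self.postings.get(term, {}).get(fld, {})

    def docs_with_term(self, term: str, fld: str) -> set[str]:
        return set(self._field_postings(term, fld))

    def docs_with_phrase(self, tokens: list[str], fld: str) -> set[str]:
        """Docs where the tokens occur at consecutive positions in ``fld``."""
        if not tokens:
            return set()
        if len(tokens) == 1:
            return self.docs_with_term(tokens[0], fld)
        candidates = self.docs_with_term(tokens[0], fld)
        for t in tokens[1:]:
            candidates &= self.docs_with_term(t, fld)
        hits = set()
        for doc_id in candidates:
            starts = set(self._field_postings(tokens[0], fld)[doc_id])
            for k, t in enumerate(tokens[1:], start=1):
                positions = self._field_postings(t, fld)[doc_id]
                starts &= {p - k for p in positions}
                if not starts:
                    break
            if starts:
                hits.add(doc_id)
        return hits

    def matching_fields_term(self, term: str) -> dict[str, set[str]]:
        """doc_id -> set of fields in which the term occurs."""
        out: dict[str, set[str]] = {}
        for fld, docs in self.postings.get(term, {}).items():
            for doc_id in docs:
                out.setdefault(doc_id, set()).add(fld)
        return out

    def docs_any_field_term(self, term: str) -> set[str]:
        """ANY-field postings: union of the term's doc sets over all fields."""
        return set(self.matching_fields_term(term))

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a directory of plain JSON files with a version header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "manifest.json").write_text(
            json.dumps(
                {
                    "format": "sectiontag-index",
                    "version": _INDEX_FORMAT_VERSION,
                    "n_docs": len(self.doc_meta),
                },
                indent=2,
            )
        )
        (directory / "doc_meta.json").write_text(json.dumps(self.doc_meta))
        (directory / "postings.json").write_text(json.dumps(self.postings))

    @classmethod
    def load(cls, directory: str | Path) -> "FieldedIndex":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("format") != "sectiontag-index":
            raise IndexingError(f"{directory} is not a sectiontag index")
        if manifest.get("version") != _INDEX_FORMAT_VERSION:
            raise IndexingError(
                f"unsupported index version {manifest.get('version')}"
            )
        index = cls()
        index.doc_meta = json.loads((directory / "doc_meta.json").read_text())
        index.postings = json.loads((directory / "postings.json").read_text())
        return index


def build_index(
    articles: Iterable[tuple[ArticleDocument, TaggedArticle]],
) -> FieldedIndex:
    """Index a corpus of (parsed document, section tags) pairs."""
    index = FieldedIndex()
    for doc, tagged in articles:
        index.add_article(doc, tagged)
    return index


# ---------------------------------------------------------------------------
# Query AST

@dataclass(frozen=True)
class Term:
    field: str | None
    token: str


@dataclass(frozen=True)
class Phrase:
    field: str | None
    tokens: tuple[str, ...]

    def __post_init__(self):
        if not self.tokens:
            raise QuerySyntaxError("empty phrase")


@dataclass(frozen=True)
class Bool:
    op: str  # AND | OR | NOT
    children: tuple["QueryNode", ...]

    def __post_init__(self):
        if self.op == "NOT":
            if len(self.children) != 1:
                raise QuerySyntaxError("NOT takes exactly one operand")
        elif self.op in ("AND", "OR"):
            if len(self.children) < 2:
                raise QuerySyntaxError(f"{self.op} takes at least two operands")
        else:
            raise QuerySyntaxError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class YearEq:
    year: int


QueryNode = Union[Term, Phrase, Bool, YearEq]


# ---------------------------------------------------------------------------
# Query parsing (recursive descent; precedence NOT > AND > OR)

_LEX_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\() |
        (?P<rparen>\)) |
        (?P<field>[A-Za-z_][A-Za-z_0-9]*)\s*: |
        (?P<quoted>"[^"]*") |
        (?P<word>[^\s()":]+)
    )""",
    re.VERBOSE,
)


def _lex(q: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(q):
        m = _LEX_RE.match(q, pos)
        if m is None:
            rest = q[pos:].strip()
            if not rest:
                break
            if '"' in rest:
                raise QuerySyntaxError("unbalanced quote in query")
            raise QuerySyntaxError(f"cannot tokenize query near {rest[:20]!r}")
        pos = m.end()
        for kind in ("lparen", "rparen", "field", "quoted", "word"):
            value = m.group(kind)
            if value is not None:
                tokens.append((kind, value))
                break
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> QueryNode:
        node = self.parse_or()
        if self.peek() is not None:
            raise QuerySyntaxError(
                f"unexpected token {self.peek()[1]!r} "
                "(unbalanced parentheses?)"
            )
        return node

    def parse_or(self) -> QueryNode:
        children = [self.parse_and()]
        while self.peek() == ("word", "OR"):
            self.advance()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Bool("OR", tuple(children))

    def parse_and(self) -> QueryNode:
        children = [self.parse_not()]
        while True:
            tok = self.peek()
            if tok == ("word", "AND"):
                self.advance()
                children.append(self.parse_not())
            elif tok is not None and tok != ("rparen", ")") and tok != ("word", "OR"):
                children.append(self.parse_not())  # adjacency = implicit AND
            else:
                break
        return children[0] if len(children) == 1 else Bool("AND", tuple(children))

    def parse_not(self) -> QueryNode:
        if self.peek() == ("word", "NOT"):
            self.advance()
            return Bool("NOT", (self.parse_not(),))
        return self.parse_atom()

    def parse_atom(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query")
        kind, value = tok
        if kind == "lparen":
            self.advance()
            node = self.parse_or()
            if self.peek() != ("rparen", ")"):
                raise QuerySyntaxError("unbalanced parentheses")
            self.advance()
            return node
        if kind == "field":
            self.advance()
            fld = value.upper()
            if fld == "PUB_YEAR":
                nxt = self.peek()
                if nxt is None or nxt[0] != "word" or not nxt[1].isdigit():
                    raise QuerySyntaxError("PUB_YEAR: expects an integer year")
                self.advance()
                return YearEq(int(nxt[1]))
            if fld not in FIELD_CODES:
                raise QueryFieldError(f"unknown field {value!r}")
            return self._term_or_phrase(fld)
        if kind in ("quoted", "word"):
            return self._term_or_phrase(None)
        raise QuerySyntaxError(f"unexpected token {value!r}")

    def _term_or_phrase(self, fld: str | None) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("expected a term after field prefix")
        kind, value = self.advance()
        if kind == "quoted":
            tokens = tuple(tokenize(value[1:-1]))
            if not tokens:
                raise QuerySyntaxError("empty quoted phrase")
            return Phrase(fld, tokens)
        if kind == "word":
            tokens = tuple(tokenize(value))
            if not tokens:
                raise QuerySyntaxError(f"term {value!r} contains no searchable tokens")
            if len(tokens) == 1:
                return Term(fld, tokens[0])
            return Phrase(fld, tokens)  # e.g. hyphenated compounds
        raise QuerySyntaxError(f"expected a term, got {value!r}")


def parse_query(q: str) -> QueryNode:
    """Parse the advanced-search dialect into a query AST.

    Grammar: uppercase AND/OR/NOT; parentheses group; ``FIELD:token`` and
    ``FIELD:"phrase"`` with FIELD a category code, TITLE or ABSTRACT;
    ``PUB_YEAR:<int>``; bare terms/phrases search the default (any) field;
    adjacency is implicit AND; precedence NOT > AND > OR.
    """
    if not q or not q.strip():
        raise QuerySyntaxError("empty query")
    tokens = _lex(q)
    if not tokens:
        raise QuerySyntaxError("empty query")
    return _Parser(tokens).parse()


# ---------------------------------------------------------------------------
# Execution

def _default_field_docs(
    index: FieldedIndex, node: Term | Phrase, include_ref_only: bool
) -> set[str]:
    """Unfielded match over all fields, minus References-only hits.

    A doc survives if it matches in at least one non-REF field (or if the
    exclusion is disabled)."""
    if isinstance(node, Term):
        matched: dict[str, set[str]] = index.matching_fields_term(node.token)
    else:
        matched = {}
        for fld in FIELD_CODES:
            for doc_id in index.docs_with_phrase(list(node.tokens), fld):
                matched.setdefault(doc_id, set()).add(fld)
    if include_ref_only:
        return set(matched)
    return {doc_id for doc_id, flds in matched.items() if flds - {"REF"}}


def execute(
    index: FieldedIndex, ast: QueryNode, include_ref_only: bool = False
) -> set[str]:
    """Evaluate a query AST to an (unranked) set of document ids.

    ``include_ref_only=True`` disables the default References-only
    exclusion for unfielded clauses (equivalent to OR-ing REF: clauses).
    NOT complements against the full indexed corpus.
    """
    if isinstance(ast, Term):
        if ast.field is None:
            return _default_field_docs(index, ast, include_ref_only)
        return index.docs_with_term(ast.token, ast.field)
    if isinstance(ast, Phrase):
        if ast.field is None:
            return _default_field_docs(index, ast, include_ref_only)
        return index.docs_with_phrase(list(ast.tokens), ast.field)
    if isinstance(ast, YearEq):
        return {
            doc_id
            for doc_id, meta in index.doc_meta.items()
            if meta.get("pub_year") == ast.year
        }
    if isinstance(ast, Bool):
        child_sets = [
            execute(index, child, include_ref_only) for child in ast.children
        ]
        if ast.op == "AND":
            out = child_sets[0]
            for s in child_sets[1:]:
                out = out & s
            return out
        if ast.op == "OR":
            out = set()
            for s in child_sets:
                out |= s
            return out
        return index.all_docs - child_sets[0]  # NOT
    raise TypeError(f"unknown query node {ast!r}")


def search(
    index: FieldedIndex, query: str, include_ref_only: bool = False
) -> list[str]:
    """Parse and execute, returning deterministically sorted doc ids."""
    return sorted(execute(index, parse_query(query), include_ref_only))
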