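"""Brute-force retrieval oracle: re-scan every document for every query.

Independent of the inverted index: matching works directly on per-section
token streams rebuilt from the parsed documents, so any disagreement with
the index implicates the index (or the oracle), not shared plumbing.
"""

from __future__ import annotations

import sectiontag as st
from sectiontag.section_index import Bool, Phrase, Term, YearEq, tokenize

FIELDS = st.FIELD_CODES


def doc_field_streams(doc, tagged):
    """field -> list of per-section token lists for one document."""
    streams: dict[str, list[list[str]]] = {}

    def add(field, tokens):
        if tokens:
            streams.setdefault(field, []).append(tokens)

    add("TITLE", tokenize(doc.title))
    if doc.abstract:
        add("ABSTRACT", tokenize(doc.abstract))
    cats = {s.path: s.categories for s in tagged.sections}
    for path, node in st.iter_sections(doc):
        tokens = tokenize(" ".join([node.heading_raw, *node.paragraphs]))
        for field in cats.get(path, ()):  # sections post under all categories
            add(field, tokens)
    return streams


def _phrase_in_stream(tokens, stream):
    n = len(tokens)
    return any(stream[i : i + n] == tokens for i in range(len(stream) - n + 1))


def _matching_fields(streams, node):
    hit = set()
    for field, sections in streams.items():
        if isinstance(node, Term):
            if any(node.token in s for s in sections):
                hit.add(field)
        else:
            tokens = list(node.tokens)
            if any(_phrase_in_stream(tokens, s) for s in sections):
                hit.add(field)
    return hit


def naive_execute(corpus, ast, include_ref_only=False):
    """Evaluate a query AST by scanning every (doc, tagged) pair."""
    all_ids = {doc.article_id for doc, _ in corpus}

    def atom_docs(node):
        out = set()
        for doc, tagged in corpus:
            streams = doc_field_streams(doc, tagged)
            if node.field is not None:
                if node.field in _matching_fields(
                    {node.field: streams.get(node.field, [])}, node
                ):
                    out.add(doc.article_id)
            else:
                fields = _matching_fields(streams, node)
                if fields and (include_ref_only or fields - {"REF"}):
                    out.add(doc.article_id)
        return out

    def run(node):
        if isinstance(node, (Term, Phrase)):
            return atom_docs(node)
        if isinstance(node, YearEq):
            return {
                doc.article_id for doc, _ in corpus if doc.pub_year == node.year
            }
        if isinstance(node, Bool):
            sets = [run(c) for c in node.children]
            if node.op == "AND":
                out = sets[0]
                for s in sets[1:]:
                    out &= s
                return out
            if node.op == "OR":
                out = set()
                for s in sets:
                    out |= s
                return out
            return all_ids - sets[0]
        raise TypeError(node)

    return run(ast)


# ---------------------------------------------------------------------------
# Random query generation over the indexed vocabulary

def corpus_vocabulary(corpus):
    vocab = set()
    for doc, tagged in corpus:
        for sections in doc_field_streams(doc, tagged).values():
            for s in sections:
                vocab.update(s)
    return sorted(vocab)


def random_query_string(rng, vocab, years, depth=0):
    """A random query in the advanced-search dialect over real terms."""
    choice = rng.random()
    if depth >= 2 or choice < 0.45:
        return _random_atom(rng, vocab, years)
    if choice < 0.60:
        return "NOT " + random_query_string(rng, vocab, years, depth + 1)
    op = " AND " if rng.random() < 0.5 else " OR "
    left = random_query_string(rng, vocab, years, depth + 1)
    right = random_query_string(rng, vocab, years, depth + 1)
    return f"({left}{op}{right})"


def _random_atom(rng, vocab, years):
    r = rng.random()
    if r < 0.10 and years:
        return f"PUB_YEAR:{years[int(rng.integers(len(years)))]}"
    field = None
    if rng.random() < 0.5:
        field = FIELDS[int(rng.integers(len(FIELDS)))]
    if rng.random() < 0.3:
        a = vocab[int(rng.integers(len(vocab)))]
        b = vocab[int(rng.integers(len(vocab)))]
        body = f'"{a} {b}"'
    else:
        body = vocab[int(rng.integers(len(vocab)))]
    return f"{field}:{body}" if field else body
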