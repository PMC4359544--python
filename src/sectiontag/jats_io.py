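"""Reading JATS/NLM full-text XML into a structured article model.

Full-text open-access articles are distributed as XML conforming to the
NISO JATS tag suite or its NLM DTD predecessors.  Section headings live in
``<title>`` elements nested inside ``<sec>`` elements; reference lists,
acknowledgements, appendices, figure and table captions and the abstract
are recognisable from the markup itself.  This module flattens that
structure into :class:`ArticleDocument`, the input to the section tagger,
and serialises tagged articles as line-delimited JSON records.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, TYPE_CHECKING

from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .section_tagger import TaggedArticle

__all__ = [
    "StructuralHint",
    "SectionNode",
    "ArticleDocument",
    "JATSParseError",
    "MissingIdentifierError",
    "UnsupportedDialectError",
    "TagConsistencyError",
    "parse_article",
    "parse_file",
    "iter_sections",
    "write_tagged",
    "read_tagged",
]


class JATSParseError(ValueError):
    """Malformed XML input; the message carries the line/column position."""


class MissingIdentifierError(ValueError):
    """The article carries no usable article identifier."""


class UnsupportedDialectError(ValueError):
    """The document root is not a JATS/NLM ``<article>``."""


class TagConsistencyError(ValueError):
    """A tagged section refers to a path absent from the document."""


class StructuralHint(enum.Enum):
    """Markup-derived role of a section node, independent of its heading."""

    BODY_SEC = "BODY_SEC"
    REF_LIST = "REF_LIST"
    FIG_CAPTION = "FIG_CAPTION"
    TABLE_CAPTION = "TABLE_CAPTION"
    ACK_BLOCK = "ACK_BLOCK"
    APP_BLOCK = "APP_BLOCK"
    ABSTRACT_BLOCK = "ABSTRACT_BLOCK"
    KWD_GROUP = "KWD_GROUP"
    NONE = "NONE"


@dataclass
class SectionNode:
    """One section-like unit: a heading, its text blocks, and child sections."""

    heading_raw: str = ""
    paragraphs: list[str] = field(default_factory=list)
    children: list["SectionNode"] = field(default_factory=list)
    structural_hint: StructuralHint = StructuralHint.BODY_SEC


@dataclass
class ArticleDocument:
    """A parsed full-text article reduced to its section structure.

    ``body`` mirrors the nesting of ``<sec>`` elements; ``back_blocks``
    holds reference lists, acknowledgements, appendices and keyword groups
    in document order; captions and the abstract are kept as separate node
    lists so structural hints survive into tagging.
    """

    article_id: str
    pub_year: int | None = None
    title: str = ""
    abstract: str = ""
    body: list[SectionNode] = field(default_factory=list)
    back_blocks: list[SectionNode] = field(default_factory=list)
    figure_captions: list[SectionNode] = field(default_factory=list)
    table_captions: list[SectionNode] = field(default_factory=list)
    abstract_block: SectionNode | None = None


# ---------------------------------------------------------------------------
# XML helpers (namespace-agnostic: OA articles appear with and without the
# JATS namespace, so matching is done on local names)

def _local(el) -> str:
    tag = el.tag
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _text(el) -> str:
    """Flatten an element to plain text, dropping inline markup."""
    return " ".join("".join(el.itertext()).split())


def _children(el, *names: str):
    for child in el:
        if _local(child) in names:
            yield child


def _find(el, *path: str):
    current = [el]
    for name in path:
        nxt = []
        for c in current:
            nxt.extend(_children(c, name))
        current = nxt
    return current[0] if current else None


def _build_sec(sec) -> SectionNode:
    node = SectionNode()
    for child in sec:
        name = _local(child)
        if name == "title":
            node.heading_raw = _text(child)
        elif name == "sec":
            node.children.append(_build_sec(child))
        elif name in ("p", "list", "disp-quote", "boxed-text"):
            text = _text(child)
            if text:
                node.paragraphs.append(text)
    return node


def _caption_node(wrap, hint: StructuralHint) -> SectionNode:
    node = SectionNode(structural_hint=hint)
    label = _find(wrap, "label")
    caption = _find(wrap, "caption")
    parts = []
    if caption is not None:
        title = _find(caption, "title")
        if title is not None:
            node.heading_raw = _text(title)
        for p in _children(caption, "p"):
            text = _text(p)
            if text:
                parts.append(text)
    if not node.heading_raw and label is not None:
        node.heading_raw = _text(label)
    node.paragraphs = parts
    return node


def parse_article(xml_text: str | bytes) -> ArticleDocument:
    """Parse one JATS/NLM article into an :class:`ArticleDocument`.

    Raises :class:`JATSParseError` on malformed XML (naming the position),
    :class:`UnsupportedDialectError` when the root element is not
    ``<article>`` and :class:`MissingIdentifierError` when no article
    identifier can be found.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise JATSParseError(f"malformed XML: {exc}") from exc

    if _local(root) != "article":
        raise UnsupportedDialectError(
            f"unsupported document dialect: root element <{_local(root)}>"
        )

    meta = _find(root, "front", "article-meta")

    article_id = ""
    if meta is not None:
        ids = list(_children(meta, "article-id"))
        for el in ids:
            if el.get("pub-id-type", "").lower() in ("pmcid", "pmc"):
                article_id = _text(el)
                break
        if not article_id and ids:
            article_id = _text(ids[0])
    if not article_id:
        raise MissingIdentifierError("article carries no <article-id>")

    pub_year: int | None = None
    if meta is not None:
        for pub_date in _children(meta, "pub-date"):
            year_el = _find(pub_date, "year")
            if year_el is not None:
                try:
                    pub_year = int(_text(year_el))
                except ValueError:
                    continue
                break

    doc = ArticleDocument(article_id=article_id, pub_year=pub_year)

    if meta is not None:
        title_el = _find(meta, "title-group", "article-title")
        if title_el is not None:
            doc.title = _text(title_el)
        abstract_el = _find(meta, "abstract")
        if abstract_el is not None:
            node = SectionNode(structural_hint=StructuralHint.ABSTRACT_BLOCK)
            for p in abstract_el.iter():
                if _local(p) == "p":
                    text = _text(p)
                    if text:
                        node.paragraphs.append(text)
            if not node.paragraphs:
                text = _text(abstract_el)
                if text:
                    node.paragraphs.append(text)
            doc.abstract = " ".join(node.paragraphs)
            doc.abstract_block = node

    body_el = _find(root, "body")
    if body_el is not None:
        for sec in _children(body_el, "sec"):
            doc.body.append(_build_sec(sec))

    back_el = _find(root, "back")
    if back_el is not None:
        for child in back_el:
            name = _local(child)
            if name == "ref-list":
                node = SectionNode(structural_hint=StructuralHint.REF_LIST)
                title = _find(child, "title")
                if title is not None:
                    node.heading_raw = _text(title)
                for ref in child.iter():
                    if _local(ref) in ("mixed-citation", "element-citation", "citation"):
                        text = _text(ref)
                        if text:
                            node.paragraphs.append(text)
                doc.back_blocks.append(node)
            elif name == "ack":
                node = _block_node(child, StructuralHint.ACK_BLOCK)
                doc.back_blocks.append(node)
            elif name == "app-group":
                for app in _children(child, "app"):
                    doc.back_blocks.append(_block_node(app, StructuralHint.APP_BLOCK))
            elif name == "app":
                doc.back_blocks.append(_block_node(child, StructuralHint.APP_BLOCK))

    if meta is not None:
        for kwd_group in _children(meta, "kwd-group"):
            node = SectionNode(structural_hint=StructuralHint.KWD_GROUP)
            title = _find(kwd_group, "title")
            if title is not None:
                node.heading_raw = _text(title)
            kwds = [_text(k) for k in _children(kwd_group, "kwd")]
            kwds = [k for k in kwds if k]
            if kwds:
                node.paragraphs.append(", ".join(kwds))
            doc.back_blocks.append(node)

    for el in root.iter():
        name = _local(el)
        if name == "fig":
            doc.figure_captions.append(
                _caption_node(el, StructuralHint.FIG_CAPTION)
            )
        elif name == "table-wrap":
            doc.table_captions.append(
                _caption_node(el, StructuralHint.TABLE_CAPTION)
            )

    return doc


def _block_node(el, hint: StructuralHint) -> SectionNode:
    node = SectionNode(structural_hint=hint)
    for child in el:
        name = _local(child)
        if name == "title":
            node.heading_raw = _text(child)
        elif name == "p":
            text = _text(child)
            if text:
                node.paragraphs.append(text)
        elif name == "sec":
            node.children.append(_build_sec(child))
    return node


def parse_file(path) -> ArticleDocument:
    with open(path, "rb") as handle:
        return parse_article(handle.read())


# ---------------------------------------------------------------------------
# Traversal

def _iter_tree(node: SectionNode, path: tuple[int, ...]):
    yield path, node
    for i, child in enumerate(node.children):
        yield from _iter_tree(child, path + (i,))


def _top_level_nodes(doc: ArticleDocument) -> list[SectionNode]:
    nodes: list[SectionNode] = []
    nodes.extend(doc.body)
    nodes.extend(doc.back_blocks)
    nodes.extend(doc.figure_captions)
    nodes.extend(doc.table_captions)
    if doc.abstract_block is not None:
        nodes.append(doc.abstract_block)
    return nodes


def iter_sections(
    doc: ArticleDocument,
) -> Iterator[tuple[tuple[int, ...], SectionNode]]:
    """Pre-order traversal over all section-like nodes of the document.

    Top-level nodes are enumerated in the order body sections, back-matter
    blocks, figure captions, table captions, abstract; ``path`` is the
    root-to-node sequence of child indices, so paths are stable identifiers
    usable in tagged output and gold annotation files.
    """
    for i, node in enumerate(_top_level_nodes(doc)):
        yield from _iter_tree(node, (i,))


# ---------------------------------------------------------------------------
# Tagged-record serialisation (line-delimited JSON; also the gold schema)

def write_tagged(doc: ArticleDocument, tags: "TaggedArticle", out: IO[str]) -> None:
    """Write one self-contained tagged-article record as a JSON line.

    Every tagged path must exist in ``doc``; reading the record back with
    :func:`read_tagged` reproduces the same (path, category set) pairs.
    """
    valid_paths = {path for path, _ in iter_sections(doc)}
    record = {
        "article_id": tags.article_id,
        "pub_year": tags.pub_year,
        "sections": [],
    }
    for section in tags.sections:
        path = tuple(section.path)
        if path not in valid_paths:
            raise TagConsistencyError(
                f"tagged path {list(path)} not present in article "
                f"{doc.article_id!r}"
            )
        record["sections"].append(
            {
                "path": list(path),
                "heading": section.heading_raw,
                "categories": sorted(section.categories),
            }
        )
    out.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_tagged(source: IO[str] | Iterable[str]) -> Iterator["TaggedArticle"]:
    """Read tagged-article records written by :func:`write_tagged`."""
    from .section_tagger import TaggedArticle, TaggedSection

    for line in source:
        line = line.strip()
        if not line:
            continue
        record = json.loads(line)
        sections = [
            TaggedSection(
                path=tuple(s["path"]),
                heading_raw=s.get("heading", ""),
                categories=frozenset(s["categories"]),
            )
            for s in record["sections"]
        ]
        yield TaggedArticle(
            article_id=record["article_id"],
            pub_year=record.get("pub_year"),
            sections=sections,
        )
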