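"""Deterministic synthetic JATS corpora with gold section annotations.

Real open-access corpora cannot be redistributed, so the tagger, corpus
statistics, evaluation and index modules are exercised on generated
articles instead.  The generator emulates the salient property of real
heading inventories — a Zipf-distributed rank-frequency curve in which a
small head of conventional headings covers most occurrences while a long
tail of idiosyncratic "custom" headings escapes any rule — and emits gold
labels that are correct by construction:

* cue headings are built from the shipped ruleset's cue phrases (plus
  verified variants that preserve the category), so their gold label is
  the matching rule's category;
* compound "X and Y" headings carry the union of both categories;
* custom headings are verified at generation time to match no rule, so
  their gold label is exactly {OTHER};
* structural blocks (reference list, figure/table captions,
  acknowledgements, appendix, keyword group, abstract) carry the gold
  label their markup implies.

Generation is a pure function of the parameter set, including the seed:
the same :class:`GeneratorParams` always yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .evaluation import GoldAnnotation
from .jats_io import ArticleDocument, StructuralHint, iter_sections, parse_article
from .section_tagger import RuleSet, default_ruleset, match_categories, normalize_heading

__all__ = [
    "GeneratorParams",
    "HeadingVocabulary",
    "build_vocabulary",
    "gen_article",
    "gen_documents",
    "gen_corpus",
]

_STRUCTURAL_KINDS = ("ref", "fig", "table", "ack", "app", "kwd")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic corpus.

    ``vocab_size`` is the number of distinct headings the Zipf draw ranges
    over; ``custom_fraction`` is the probability that a drawn heading is a
    custom (unmatchable) one, realised by assigning that share of the Zipf
    probability mass to the rare (tail) ranks; ``compound_fraction`` is
    the probability that a cue heading joins two cue phrases of different
    categories with " and ".
    """

    n_articles: int = 100
    sections_min: int = 4
    sections_max: int = 8
    zipf_exponent: float = 1.0
    vocab_size: int = 500
    custom_fraction: float = 0.1
    compound_fraction: float = 0.0
    include_structural: tuple[str, ...] = ("ref", "fig", "table", "ack", "kwd")
    include_abstract: bool = True
    year_min: int = 2008
    year_max: int = 2015
    marker_tokens: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.custom_fraction <= 1.0:
            raise ValueError("custom_fraction must lie in [0, 1]")
        if not 0.0 <= self.compound_fraction <= 1.0:
            raise ValueError("compound_fraction must lie in [0, 1]")
        if self.vocab_size < 3:
            raise ValueError("vocab_size must be >= 3")
        if self.sections_min < 0 or self.sections_max < self.sections_min:
            raise ValueError("invalid sections_min/sections_max range")
        unknown = set(self.include_structural) - set(_STRUCTURAL_KINDS)
        if unknown:
            raise ValueError(f"unknown structural kinds {sorted(unknown)}")
        if self.year_max < self.year_min:
            raise ValueError("invalid year range")


@dataclass(frozen=True)
class HeadingVocabulary:
    """Rank-ordered heading vocabulary with aligned gold category sets."""

    phrases: tuple[str, ...]
    gold: tuple[frozenset[str], ...]  # gold[i] for rank i+1
    probs: tuple[float, ...]  # exact Zipf pmf over ranks
    cue_ranks: tuple[int, ...]  # 0-based ranks holding cue headings


# -- vocabulary construction -------------------------------------------------

_CUE_VARIANT_SUFFIXES = (
    "overview",
    "details",
    "considerations",
    "perspectives",
    "approaches",
    "framework",
    "aspects",
    "context",
    "examples",
    "notes",
)

_CUSTOM_MODS = (
    "source",
    "clinical",
    "regional",
    "longitudinal",
    "curated",
    "public",
    "national",
    "archived",
    "combined",
    "preliminary",
    "historical",
    "external",
)

_CUSTOM_NOUNS = (
    "database",
    "cohort",
    "pipeline",
    "registry",
    "workflow",
    "annotation",
    "corpus",
    "ontology",
    "curation",
    "archive",
    "repository",
    "dataset",
    "protocol",
    "specimen",
    "assay",
    "genome",
    "panel",
    "catalogue",
    "atlas",
    "taxonomy",
)

_CUSTOM_SUFFIXES = ("overview", "commentary", "outlook", "profile", "landscape")


def _cue_phrases(ruleset: RuleSet) -> list[tuple[str, frozenset[str]]]:
    """Base cue phrases plus category-preserving variants, gold attached."""
    out: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    base: list[tuple[str, frozenset[str]]] = []
    for pattern, _code in ruleset.all_patterns():
        if pattern in seen:
            continue
        seen.add(pattern)
        cats = frozenset(match_categories(pattern, ruleset))
        if cats:
            base.append((pattern, cats))
    out.extend(base)
    for suffix in _CUE_VARIANT_SUFFIXES:
        for pattern, cats in base:
            variant = f"{pattern} {suffix}"
            if variant in seen:
                continue
            # the variant must not trigger any additional rule
            if frozenset(match_categories(normalize_heading(variant), ruleset)) == cats:
                seen.add(variant)
                out.append((variant, cats))
    return out


def _custom_phrases(ruleset: RuleSet, needed: int) -> list[str]:
    """Headings guaranteed to match no rule (gold = {OTHER})."""
    out: list[str] = []
    candidates = itertools.chain(
        ["source data and the content of the database"],
        (
            f"{mod} {noun} {suffix}"
            for suffix in _CUSTOM_SUFFIXES
            for mod in _CUSTOM_MODS
            for noun in _CUSTOM_NOUNS
        ),
    )
    for phrase in candidates:
        if len(out) >= needed:
            return out
        if not match_categories(normalize_heading(phrase), ruleset):
            out.append(phrase)
    i = 0
    while len(out) < needed:
        phrase = f"topic profile {i}"
        if not match_categories(normalize_heading(phrase), ruleset):
            out.append(phrase)
        i += 1
    return out


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    weights = ranks ** (-exponent)
    return weights / weights.sum()


@lru_cache(maxsize=16)
def _vocabulary_cached(
    vocab_size: int, custom_fraction: float, zipf_exponent: float
) -> HeadingVocabulary:
    ruleset = default_ruleset()
    probs = _zipf_probs(vocab_size, zipf_exponent)

    # assign ~custom_fraction of the probability mass to custom headings,
    # filling from the rarest rank upward so the head of the distribution
    # stays conventional (as in real corpora) and the mass error is at most
    # the pmf at the boundary rank
    custom_ranks: set[int] = set()
    mass = 0.0
    for rank in range(vocab_size - 1, -1, -1):
        if mass + probs[rank] > custom_fraction + 1e-12:
            break
        custom_ranks.add(rank)
        mass += probs[rank]
    if custom_fraction >= 1.0:
        custom_ranks = set(range(vocab_size))

    cue_slots = [r for r in range(vocab_size) if r not in custom_ranks]
    cue_pool = _cue_phrases(ruleset)
    if len(cue_pool) < len(cue_slots):
        raise ValueError(
            f"vocabulary needs {len(cue_slots)} cue headings but only "
            f"{len(cue_pool)} are derivable from the ruleset; "
            "reduce vocab_size or raise custom_fraction"
        )
    custom_pool = _custom_phrases(ruleset, len(custom_ranks))

    phrases: list[str] = [""] * vocab_size
    gold: list[frozenset[str]] = [frozenset()] * vocab_size
    for slot, (phrase, cats) in zip(cue_slots, cue_pool):
        phrases[slot] = phrase
        gold[slot] = cats
    for slot, phrase in zip(sorted(custom_ranks), custom_pool):
        phrases[slot] = phrase
        gold[slot] = frozenset({"OTHER"})

    return HeadingVocabulary(
        phrases=tuple(phrases),
        gold=tuple(gold),
        probs=tuple(float(p) for p in probs),
        cue_ranks=tuple(cue_slots),
    )


def build_vocabulary(params: GeneratorParams) -> HeadingVocabulary:
    """The rank-ordered heading vocabulary implied by ``params``."""
    return _vocabulary_cached(
        params.vocab_size, params.custom_fraction, params.zipf_exponent
    )


# -- article assembly --------------------------------------------------------

_FILLER = (
    "the observed signal was stable across replicates",
    "samples were processed in randomised batches",
    "values are reported with their dispersion",
    "the assay was repeated under matched conditions",
    "no systematic drift was detected over time",
)


def _draw_sections(
    rng: np.random.Generator, params: GeneratorParams, vocab: HeadingVocabulary
) -> list[tuple[str, frozenset[str]]]:
    n = int(rng.integers(params.sections_min, params.sections_max + 1))
    probs = np.asarray(vocab.probs)
    out: list[tuple[str, frozenset[str]]] = []
    for _ in range(n):
        if (
            params.compound_fraction > 0
            and len(vocab.cue_ranks) >= 2
            and rng.random() < params.compound_fraction
        ):
            a, b = rng.choice(len(vocab.cue_ranks), size=2, replace=False)
            ra, rb = vocab.cue_ranks[a], vocab.cue_ranks[b]
            if vocab.gold[ra] != vocab.gold[rb]:
                heading = f"{vocab.phrases[ra]} and {vocab.phrases[rb]}"
                out.append((heading, vocab.gold[ra] | vocab.gold[rb]))
                continue
        rank = int(rng.choice(len(probs), p=probs))
        out.append((vocab.phrases[rank], vocab.gold[rank]))
    return out


def _marker_text(params: GeneratorParams, cats: frozenset[str]) -> str:
    tokens = [tok for tok, code in params.marker_tokens if code in cats]
    return " ".join(tokens)


def _article_xml(
    article_id: str,
    year: int,
    sections: list[tuple[str, frozenset[str]]],
    params: GeneratorParams,
    rng: np.random.Generator,
) -> str:
    inc = set(params.include_structural)
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="UTF-8"?>')
    parts.append('<article article-type="research-article">')
    parts.append("<front><article-meta>")
    parts.append(f'<article-id pub-id-type="pmcid">{escape(article_id)}</article-id>')
    parts.append(
        "<title-group><article-title>A synthetic study of "
        f"record {escape(article_id)}</article-title></title-group>"
    )
    parts.append(f"<pub-date><year>{year}</year></pub-date>")
    if params.include_abstract:
        parts.append(
            "<abstract><p>synthetic abstract summarising the record "
            f"{_marker_text(params, frozenset({'OTHER'}))}</p></abstract>"
        )
    if "kwd" in inc:
        kw_marker = _marker_text(params, frozenset({"KEYWORDS"}))
        parts.append(
            "<kwd-group><kwd>synthetic</kwd><kwd>benchmark</kwd>"
            f"<kwd>{escape(kw_marker) or 'corpus'}</kwd></kwd-group>"
        )
    parts.append("</article-meta></front>")

    parts.append("<body>")
    for heading, cats in sections:
        filler = _FILLER[int(rng.integers(len(_FILLER)))]
        marker = _marker_text(params, cats)
        text = f"{filler} {marker}".strip()
        parts.append(
            f"<sec><title>{escape(heading.capitalize())}</title>"
            f"<p>{escape(text)}</p></sec>"
        )
    if "fig" in inc:
        marker = _marker_text(params, frozenset({"FIG"}))
        parts.append(
            '<fig id="f1"><label>Fig 1</label><caption>'
            f"<p>synthetic panel of the measured response {escape(marker)}</p>"
            "</caption></fig>"
        )
    if "table" in inc:
        marker = _marker_text(params, frozenset({"TABLE"}))
        parts.append(
            '<table-wrap id="t1"><label>Tab 1</label><caption>'
            f"<p>synthetic tabulated measurements {escape(marker)}</p>"
            "</caption></table-wrap>"
        )
    parts.append("</body>")

    back: list[str] = []
    if "ack" in inc:
        marker = _marker_text(params, frozenset({"ACK"}))
        back.append(
            "<ack><title>Acknowledgements</title>"
            f"<p>we thank the synthetic consortium {escape(marker)}</p></ack>"
        )
    if "app" in inc:
        marker = _marker_text(params, frozenset({"APPENDIX"}))
        back.append(
            "<app-group><app><title>Appendix A</title>"
            f"<p>synthetic derivations {escape(marker)}</p></app></app-group>"
        )
    if "ref" in inc:
        marker = _marker_text(params, frozenset({"REF"}))
        citations = [
            f"Author A. A synthetic citation {i}. J Synth Data. {year - 1}. "
            f"{marker}".strip()
            for i in (1, 2)
        ]
        refs = "".join(
            f"<ref><mixed-citation>{escape(c)}</mixed-citation></ref>"
            for c in citations
        )
        back.append(f"<ref-list><title>References</title>{refs}</ref-list>")
    if back:
        parts.append("<back>" + "".join(back) + "</back>")
    parts.append("</article>")
    return "\n".join(parts)


_HINT_GOLD = {
    StructuralHint.REF_LIST: frozenset({"REF"}),
    StructuralHint.FIG_CAPTION: frozenset({"FIG"}),
    StructuralHint.TABLE_CAPTION: frozenset({"TABLE"}),
    StructuralHint.ACK_BLOCK: frozenset({"ACK"}),
    StructuralHint.APP_BLOCK: frozenset({"APPENDIX"}),
    StructuralHint.KWD_GROUP: frozenset({"KEYWORDS"}),
    StructuralHint.ABSTRACT_BLOCK: frozenset({"OTHER"}),
}


def _gen_one(
    rng: np.random.Generator, params: GeneratorParams, article_id: str
) -> tuple[str, ArticleDocument, list[GoldAnnotation]]:
    vocab = build_vocabulary(params)
    year = int(rng.integers(params.year_min, params.year_max + 1))
    sections = _draw_sections(rng, params, vocab)
    xml = _article_xml(article_id, year, sections, params, rng)
    doc = parse_article(xml)

    body_gold = [cats for _, cats in sections]
    gold: list[GoldAnnotation] = []
    body_idx = 0
    for path, node in iter_sections(doc):
        if node.structural_hint is StructuralHint.BODY_SEC:
            cats = body_gold[body_idx]
            body_idx += 1
        else:
            cats = _HINT_GOLD[node.structural_hint]
        gold.append(
            GoldAnnotation(article_id=article_id, section_path=path, categories=cats)
        )
    assert body_idx == len(body_gold)
    return xml, doc, gold


def gen_article(
    rng: np.random.Generator, params: GeneratorParams, article_id: str = "PMC9000001"
) -> tuple[str, list[GoldAnnotation]]:
    """Generate one well-formed JATS article and its gold annotations.

    Gold paths align with the traversal of the parsed article, so the
    output plugs directly into the evaluation module.
    """
    xml, _doc, gold = _gen_one(rng, params, article_id)
    return xml, gold


def gen_documents(
    params: GeneratorParams,
):
    """Yield (parsed document, gold annotations) for a whole corpus.

    In-memory counterpart of :func:`gen_corpus` for tests and pipelines
    that do not need files on disk.  Deterministic in ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    for i in range(params.n_articles):
        article_id = f"PMC{9000001 + i}"
        _xml, doc, gold = _gen_one(rng, params, article_id)
        yield doc, gold


def gen_corpus(
    params: GeneratorParams, out_dir: str | Path, force: bool = False
) -> dict:
    """Write a corpus directory: one .xml per article, gold.jsonl, manifest.

    Refuses a non-empty output directory unless ``force`` is set.  Running
    twice with the same params produces byte-identical files.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(params.seed)
    gold_lines: list[str] = []
    files: list[str] = []
    for i in range(params.n_articles):
        article_id = f"PMC{9000001 + i}"
        xml, doc, gold = _gen_one(rng, params, article_id)
        filename = f"{article_id}.xml"
        (out_dir / filename).write_text(xml, encoding="utf-8")
        files.append(filename)
        headings = {path: node.heading_raw for path, node in iter_sections(doc)}
        record = {
            "article_id": article_id,
            "pub_year": doc.pub_year,
            "sections": [
                {
                    "path": list(g.section_path),
                    "heading": headings[g.section_path],
                    "categories": sorted(g.categories),
                }
                for g in gold
            ],
        }
        gold_lines.append(json.dumps(record, ensure_ascii=False))

    (out_dir / "gold.jsonl").write_text("\n".join(gold_lines) + "\n", encoding="utf-8")
    manifest = {
        "generator": "sectiontag.fixtures",
        "params": dataclasses.asdict(params),
        "n_files": len(files),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return manifest
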