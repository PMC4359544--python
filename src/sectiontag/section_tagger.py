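"""Rule-based categorisation of article sections into 17 categories.

Sections of a full-text article are assigned to a fixed inventory of
17 discourse-level categories (Introduction & Background, Materials &
Methods, Results, Discussion, Conclusion & Future Work, Case Report,
Acknowledgement & Funding, Author Contribution, Competing Interest,
Supplementary Data, Abbreviations, Keywords, References, Figures, Tables,
Appendix, and the fallback Other).  Categorisation is driven by the
section heading: each of the 16 substantive categories owns an ordered
list of cue phrases, and a heading matching cue phrases of several
categories (e.g. "Results and Discussion") is assigned to all of them.
Structural cues from the XML (reference lists, figure and table captions,
acknowledgement and appendix blocks, keyword groups) categorise content
that carries no conventional heading.  Headings matching no rule fall
back to Other.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .jats_io import ArticleDocument, SectionNode, StructuralHint, iter_sections

__all__ = [
    "SectionCategory",
    "CATEGORY_CODES",
    "CATEGORY_LABELS",
    "Rule",
    "RuleSet",
    "RuleConfigError",
    "TaggedSection",
    "TaggedArticle",
    "normalize_heading",
    "match_categories",
    "assign_structural",
    "tag_article",
    "load_ruleset",
    "default_ruleset",
]


class SectionCategory(str, enum.Enum):
    """The 17 section categories; ``OTHER`` is the unique fallback."""

    INTRO = "INTRO"
    METHODS = "METHODS"
    RESULTS = "RESULTS"
    DISCUSSION = "DISCUSSION"
    CONCL = "CONCL"
    CASE = "CASE"
    ACK = "ACK"
    AUTH_CON = "AUTH_CON"
    COMP_INT = "COMP_INT"
    SUPPL = "SUPPL"
    ABBR = "ABBR"
    KEYWORDS = "KEYWORDS"
    REF = "REF"
    FIG = "FIG"
    TABLE = "TABLE"
    APPENDIX = "APPENDIX"
    OTHER = "OTHER"


CATEGORY_LABELS: dict[str, str] = {
    "INTRO": "Introduction & Background",
    "METHODS": "Materials & Methods",
    "RESULTS": "Results",
    "DISCUSSION": "Discussion",
    "CONCL": "Conclusion & Future Work",
    "CASE": "Case Report",
    "ACK": "Acknowledgement & Funding",
    "AUTH_CON": "Author Contribution",
    "COMP_INT": "Competing Interest",
    "SUPPL": "Supplementary Data",
    "ABBR": "Abbreviations",
    "KEYWORDS": "Keywords",
    "REF": "References",
    "FIG": "Figures",
    "TABLE": "Tables",
    "APPENDIX": "Appendix",
    "OTHER": "Other",
}

CATEGORY_CODES: tuple[str, ...] = tuple(CATEGORY_LABELS)

_STRUCTURAL_MAP: dict[StructuralHint, frozenset[str]] = {
    StructuralHint.REF_LIST: frozenset({"REF"}),
    StructuralHint.FIG_CAPTION: frozenset({"FIG"}),
    StructuralHint.TABLE_CAPTION: frozenset({"TABLE"}),
    StructuralHint.ACK_BLOCK: frozenset({"ACK"}),
    StructuralHint.APP_BLOCK: frozenset({"APPENDIX"}),
    StructuralHint.KWD_GROUP: frozenset({"KEYWORDS"}),
    StructuralHint.ABSTRACT_BLOCK: frozenset({"OTHER"}),
    StructuralHint.BODY_SEC: frozenset(),
    StructuralHint.NONE: frozenset(),
}


class RuleConfigError(ValueError):
    """The ruleset config is structurally invalid."""


# ---------------------------------------------------------------------------
# Heading normalisation

# leading enumeration tokens: "1.", "2.3", "IV." — a delimiter (./):) is
# required so stripping can never re-fire on already-normalised text
_ENUM_RE = re.compile(
    r"^\s*(?:\d+(?:\.\d+)+[.):]?|\d+[.):]|[IVXLCDMivxlcdm]+[.)])\s+"
)
_PUNCT_RE = re.compile(r"[^\w\s&]|_")
_WS_RE = re.compile(r"\s+")


def normalize_heading(text: str) -> str:
    """Canonicalise a heading for rule matching.

    Case-folds; strips leading enumeration tokens ("1.", "2.3", "IV.");
    removes punctuation except internal ampersands; collapses whitespace.
    Empty input stays empty.
    """
    s = text or ""
    while True:
        m = _ENUM_RE.match(s)
        if m is None:
            break
        s = s[m.end():]
    s = s.casefold()
    s = _PUNCT_RE.sub(" ", s)
    return _WS_RE.sub(" ", s).strip()


# ---------------------------------------------------------------------------
# Rules

@dataclass(frozen=True)
class Rule:
    """Cue-phrase patterns for one category (never for OTHER)."""

    category: str
    patterns: tuple[str, ...]

    def __post_init__(self):
        if self.category == "OTHER":
            raise RuleConfigError("the OTHER fallback cannot carry patterns")
        if self.category not in CATEGORY_CODES:
            raise RuleConfigError(f"unknown category code {self.category!r}")
        if not self.patterns or any(not p for p in self.patterns):
            raise RuleConfigError(
                f"rule for {self.category} has an empty pattern list or pattern"
            )


def _compile_pattern(pattern: str) -> re.Pattern:
    # whole-word-bounded contiguous phrase; each word tolerates a plural -s
    # so "concluding remark" matches "Concluding remarks" but "discussion"
    # never matches "discussant"
    words = [re.escape(w) + r"s?" for w in pattern.split()]
    return re.compile(r"\b" + r" ".join(words) + r"\b")


@dataclass
class RuleSet:
    """Ordered cue-phrase rules per category, loaded from a config file."""

    rules: dict[str, Rule]
    provenance: str = ""

    def __post_init__(self):
        self._compiled: dict[str, list[re.Pattern]] = {
            code: [_compile_pattern(p) for p in rule.patterns]
            for code, rule in self.rules.items()
        }

    def all_patterns(self) -> list[tuple[str, str]]:
        """Every (pattern, category code) pair, in config order."""
        return [
            (p, code)
            for code, rule in self.rules.items()
            for p in rule.patterns
        ]

    def match(self, heading_norm: str) -> set[str]:
        if not heading_norm:
            return set()
        return {
            code
            for code, compiled in self._compiled.items()
            if any(rx.search(heading_norm) for rx in compiled)
        }


def match_categories(heading_norm: str, ruleset: RuleSet) -> set[str]:
    """Categories whose cue phrases occur (word-bounded) in the heading.

    Returns the empty set when no rule matches; the caller applies the
    OTHER fallback.
    """
    return ruleset.match(heading_norm)


def load_ruleset(config: str | Path) -> RuleSet:
    """Load and validate a category → cue-phrase-list config (YAML)."""
    path = Path(config)
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return _ruleset_from_mapping(raw, provenance=str(path))


def _ruleset_from_mapping(raw, provenance: str) -> RuleSet:
    if not isinstance(raw, dict):
        raise RuleConfigError("ruleset config must be a mapping of category to patterns")
    rules: dict[str, Rule] = {}
    for code, patterns in raw.items():
        code = str(code)
        if code not in CATEGORY_CODES:
            raise RuleConfigError(f"unknown category code {code!r}")
        if code == "OTHER":
            raise RuleConfigError("config may not define patterns for OTHER")
        if not isinstance(patterns, list) or not patterns:
            raise RuleConfigError(f"category {code}: empty or non-list pattern list")
        norm_patterns = []
        for p in patterns:
            norm = normalize_heading(str(p))
            if not norm:
                raise RuleConfigError(f"category {code}: pattern {p!r} normalises to empty")
            norm_patterns.append(norm)
        rules[code] = Rule(category=code, patterns=tuple(norm_patterns))
    return RuleSet(rules=rules, provenance=provenance)


@lru_cache(maxsize=1)
def default_ruleset() -> RuleSet:
    """The ruleset shipped with the package (``rules/default.yaml``)."""
    ref = resources.files("sectiontag").joinpath("rules/default.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _ruleset_from_mapping(raw, provenance="sectiontag:rules/default.yaml")


# ---------------------------------------------------------------------------
# Tagging

@dataclass(frozen=True)
class TaggedSection:
    """Category assignment for one section, addressed by its path."""

    path: tuple[int, ...]
    heading_raw: str
    categories: frozenset[str]

    def __post_init__(self):
        if not self.categories:
            raise ValueError("categories must be non-empty")
        if "OTHER" in self.categories and len(self.categories) > 1:
            raise ValueError("OTHER only appears as a singleton category set")


@dataclass
class TaggedArticle:
    """All section tags of one article plus the aggregate category set."""

    article_id: str
    pub_year: int | None
    sections: list[TaggedSection] = field(default_factory=list)

    @property
    def present_categories(self) -> frozenset[str]:
        out: set[str] = set()
        for section in self.sections:
            out |= section.categories
        return frozenset(out)


def assign_structural(node: SectionNode) -> set[str]:
    """Categories implied by the node's XML role alone."""
    return set(_STRUCTURAL_MAP[node.structural_hint])


def tag_article(doc: ArticleDocument, ruleset: RuleSet | None = None) -> TaggedArticle:
    """Tag every section of a parsed article.

    For each node the category set is the union of structural cues and
    heading-rule matches.  A node left uncategorised inherits the nearest
    ancestor's non-OTHER categories (a "Cell culture" subsection under
    "Methods" stays retrievable as METHODS); with no such ancestor it is
    tagged {OTHER}.  Deterministic for fixed inputs.
    """
    if ruleset is None:
        ruleset = default_ruleset()

    tagged: list[TaggedSection] = []

    def visit(node: SectionNode, path: tuple[int, ...], inherited: frozenset[str]):
        cats = assign_structural(node) | match_categories(
            normalize_heading(node.heading_raw), ruleset
        )
        if not cats:
            cats = set(inherited) or {"OTHER"}
        tagged.append(
            TaggedSection(
                path=path,
                heading_raw=node.heading_raw,
                categories=frozenset(cats),
            )
        )
        child_inherit = frozenset(cats - {"OTHER"}) or inherited
        for i, child in enumerate(node.children):
            visit(child, path + (i,), child_inherit)

    # mirror iter_sections ordering so paths line up with the traversal
    for (path, node) in iter_sections(doc):
        if len(path) > 1:
            continue  # children are visited recursively below
        visit(node, path, frozenset())

    return TaggedArticle(
        article_id=doc.article_id, pub_year=doc.pub_year, sections=tagged
    )
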