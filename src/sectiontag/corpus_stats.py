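"""Corpus-level heading statistics: rank-frequency tables, Zipf diagnostics,
top-k mass and per-category presence.

The distribution of natural-language section headings across a large
article corpus is heavy-tailed and well described by Zipf's law
(count ∝ rank^(−s)), which is why a modest number of cue phrases covers
the bulk of heading occurrences.  These diagnostics quantify that on any
corpus: how concentrated the heading mass is in the top-k headings, and
how close the empirical rank-frequency curve is to a power law.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .jats_io import ArticleDocument, iter_sections
from .section_tagger import CATEGORY_CODES, TaggedArticle, normalize_heading

__all__ = [
    "HeadingFrequencyTable",
    "CategoryPresenceReport",
    "EmptyCorpusError",
    "heading_frequencies",
    "top_k_mass",
    "zipf_slope",
    "category_presence",
]


class EmptyCorpusError(ValueError):
    """The corpus contains no articles (or no data to aggregate)."""


@dataclass
class HeadingFrequencyTable:
    """Normalised headings with counts, sorted by descending count.

    Ties in count break lexicographically so that rank assignment (and
    everything derived from it) is deterministic.
    """

    entries: list[tuple[str, int]]
    total: int


@dataclass
class CategoryPresenceReport:
    """Fraction of articles containing at least one section per category."""

    per_category: dict[str, float]
    n_articles: int


def heading_frequencies(
    corpus: Iterable[ArticleDocument],
) -> HeadingFrequencyTable:
    """Count normalised section headings across a corpus.

    Empty headings (untitled structural blocks) are excluded.  Invariant
    to article order.
    """
    counts: Counter[str] = Counter()
    n_articles = 0
    for doc in corpus:
        n_articles += 1
        for _, node in iter_sections(doc):
            heading = normalize_heading(node.heading_raw)
            if heading:
                counts[heading] += 1
    if n_articles == 0:
        raise EmptyCorpusError("empty corpus")
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return HeadingFrequencyTable(entries=entries, total=sum(counts.values()))


def top_k_mass(table: HeadingFrequencyTable, k: int) -> float:
    """Fraction of all heading occurrences covered by the top-k headings."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not table.entries:
        raise EmptyCorpusError("empty frequency table")
    top = sum(count for _, count in table.entries[:k])
    return top / table.total


def zipf_slope(table: HeadingFrequencyTable) -> tuple[float, float]:
    """OLS fit of log(count) against log(rank).

    Returns ``(slope, r_squared)``; an exact Zipf table (count ∝ 1/rank)
    gives slope −1 with r² = 1.  Requires at least 3 ranks.  When all
    counts are equal the slope is 0 and r² is reported as 1 (the constant
    fit is exact).
    """
    if len(table.entries) < 3:
        raise EmptyCorpusError(
            f"need >= 3 distinct ranks for a Zipf fit, got {len(table.entries)}"
        )
    counts = np.array([c for _, c in table.entries], dtype=float)
    ranks = np.arange(1, len(counts) + 1, dtype=float)
    x, y = np.log(ranks), np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r_squared)


def category_presence(
    corpus: Iterable[TaggedArticle],
) -> CategoryPresenceReport:
    """Per-category fraction of articles with >= 1 section of that category.

    Presence is binary per article, so the report describes how many
    articles expose each section type, not how many sections exist.
    """
    n_articles = 0
    hits: Counter[str] = Counter()
    for article in corpus:
        n_articles += 1
        for code in article.present_categories:
            hits[code] += 1
    if n_articles == 0:
        raise EmptyCorpusError("empty corpus")
    per_category = {
        code: hits.get(code, 0) / n_articles for code in CATEGORY_CODES
    }
    return CategoryPresenceReport(per_category=per_category, n_articles=n_articles)
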