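"""Scoring predicted section tags against gold annotations.

The unit of evaluation is the (article, section, category) triple under
multi-label scoring: a "Results and Discussion" section carrying both
codes contributes two decisions.  Counts are pooled per category and
micro-averaged into precision, recall and F-score; zero denominators are
reported as undefined rather than coerced to 0 or 100, so empty corpora
cannot silently inflate scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .section_tagger import TaggedArticle

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "PRF",
    "PRFReport",
    "AlignmentError",
    "read_gold",
    "score",
    "prf",
    "harmonic_f",
]


class AlignmentError(ValueError):
    """Gold refers to articles or section paths absent from the prediction."""


@dataclass(frozen=True)
class GoldAnnotation:
    """Ground-truth category set for one section of one article."""

    article_id: str
    section_path: tuple[int, ...]
    categories: frozenset[str]


@dataclass
class ConfusionCounts:
    """Per-category and pooled true-positive / false-positive / false-negative
    counts."""

    per_category: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def totals(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_category.values())
        fp = sum(v[1] for v in self.per_category.values())
        fn = sum(v[2] for v in self.per_category.values())
        return tp, fp, fn


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F as percentages rounded to two decimals.

    A value is ``None`` when its denominator is zero (undefined, not 0)."""

    precision: float | None
    recall: float | None
    f_score: float | None


@dataclass
class PRFReport:
    micro: PRF
    per_category: dict[str, PRF]


def read_gold(source: str | Path | IO[str]) -> list[GoldAnnotation]:
    """Read gold annotations from a line-delimited JSON file.

    The schema is the tagged-record schema (one JSON object per article
    with ``article_id`` and ``sections``), so a curated tag file is
    directly usable as gold.  (article_id, path) pairs must be unique.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            return read_gold(handle)
    gold: list[GoldAnnotation] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for line in source:
        line = line.strip()
        if not line:
            continue
        record = json.loads(line)
        for section in record["sections"]:
            key = (record["article_id"], tuple(section["path"]))
            if key in seen:
                raise ValueError(f"duplicate gold entry for {key}")
            seen.add(key)
            gold.append(
                GoldAnnotation(
                    article_id=key[0],
                    section_path=key[1],
                    categories=frozenset(section["categories"]),
                )
            )
    return gold


def score(
    predicted: Iterable[TaggedArticle], gold: Iterable[GoldAnnotation]
) -> ConfusionCounts:
    """Compare predicted tags with gold at the (article, section, category)
    level.

    Every gold (article, path) must resolve to a predicted section;
    unresolvable references raise :class:`AlignmentError` listing the
    offenders.  Predicted articles with no gold at all are ignored with a
    warning.  OTHER participates like any other category, so tagging a
    METHODS section as OTHER costs one false negative and one false
    positive.
    """
    gold = list(gold)
    gold_articles = {g.article_id for g in gold}

    pred_triples: set[tuple[str, tuple[int, ...], str]] = set()
    pred_paths: set[tuple[str, tuple[int, ...]]] = set()
    for article in predicted:
        if article.article_id not in gold_articles:
            warnings.warn(
                f"prediction for article {article.article_id!r} has no gold "
                "annotations; ignored",
                stacklevel=2,
            )
            continue
        for section in article.sections:
            pred_paths.add((article.article_id, section.path))
            for code in section.categories:
                pred_triples.add((article.article_id, section.path, code))

    missing = [
        (g.article_id, list(g.section_path))
        for g in gold
        if (g.article_id, g.section_path) not in pred_paths
    ]
    if missing:
        raise AlignmentError(
            f"gold refers to unknown article/section pairs: {missing[:20]}"
        )

    gold_triples = {
        (g.article_id, g.section_path, code)
        for g in gold
        for code in g.categories
    }

    counts = ConfusionCounts()
    codes = {t[2] for t in pred_triples | gold_triples}
    for code in sorted(codes):
        tp = sum(1 for t in pred_triples & gold_triples if t[2] == code)
        fp = sum(1 for t in pred_triples - gold_triples if t[2] == code)
        fn = sum(1 for t in gold_triples - pred_triples if t[2] == code)
        counts.per_category[code] = (tp, fp, fn)
    return counts


def _prf_from(tp: int, fp: int, fn: int) -> PRF:
    precision = tp / (tp + fp) * 100.0 if tp + fp else None
    recall = tp / (tp + fn) * 100.0 if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f = None
    else:
        f = 2 * precision * recall / (precision + recall)
    return PRF(
        precision=None if precision is None else round(precision, 2),
        recall=None if recall is None else round(recall, 2),
        f_score=None if f is None else round(f, 2),
    )


def prf(counts: ConfusionCounts) -> PRFReport:
    """Micro-averaged and per-category precision, recall and F-score."""
    micro = _prf_from(*counts.totals)
    per_category = {
        code: _prf_from(*vals) for code, vals in sorted(counts.per_category.items())
    }
    return PRFReport(micro=micro, per_category=per_category)


def harmonic_f(precision_pct: float, recall_pct: float) -> float:
    """F-score (harmonic mean, %) of precision and recall given in %,
    rounded to two decimals."""
    if precision_pct + recall_pct == 0:
        raise ValueError("precision and recall are both zero; F undefined")
    return round(
        2 * precision_pct * recall_pct / (precision_pct + recall_pct), 2
    )
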