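# Methods

This note documents the models, conventions and design choices behind
`sectiontag`: what the tagger, evaluator, index and synthetic-corpus
generator actually compute, which knobs matter, and what the test results
do and do not establish about behaviour on real corpora.

## Document model

`parse_article` accepts any XML whose root element is `<article>` — this
covers NISO JATS 1.x and the NLM DTD 2.3/3.0 lineage — and rejects other
roots explicitly rather than guessing. Matching is namespace-agnostic
(articles circulate both with and without the JATS namespace). The parse
reduces an article to section-like nodes: the `<sec>` tree of the body
(headings from `<title>`, inline markup flattened to text), and
structural blocks — reference lists, acknowledgements, appendices,
keyword groups, figure and table captions, the abstract — each carrying a
`structural_hint`. The article identifier prefers a PMC id and falls back
to the first `<article-id>`; a missing id is an error, because every
downstream artefact (tags, gold, postings) is keyed by it. `pub_year`
comes from the first `<pub-date>` with a parsable `<year>`; articles
without one are simply never returned by `PUB_YEAR:` filters.

Sections are addressed by *path*: the root-to-node sequence of child
indices under a fixed top-level ordering (body sections, back-matter
blocks, figure captions, table captions, abstract). Paths are the join
key between tagged output, gold files and evaluation, so the traversal
order is part of the file-format contract.

## Tagging

Heading normalisation case-folds, strips leading enumeration tokens
("1.", "2.3", "IV." — a delimiter character is required, so normalisation
is idempotent and a bare leading number like "2,4-dinitrophenol" is left
alone), removes punctuation except internal ampersands, and collapses
whitespace.

Rule matching treats each cue phrase as a whole-word-bounded contiguous
phrase anywhere in the normalised heading: "general discussion" matches
the `discussion` rule, "discussant" does not. Each pattern word tolerates
a plural `-s` so that "Concluding remarks" matches `concluding remark`
and "Conflicts of interest" matches `conflict of interest`; no other
stemming is attempted. A heading's category set is the union over all
matching rules, which makes compound headings ("Results and Discussion")
multi-label by construction.

Structural hints are united with (not replaced by) heading matches:
reference lists, captions, acknowledgements, appendices and keyword
groups are categorised even when untitled, and a titled block simply
confirms its structural category. The abstract is tagged `OTHER` — it is
not one of the 16 substantive section types — while remaining separately
searchable through the index's `ABSTRACT` field.

Sections that still have no category inherit the nearest ancestor's
non-`OTHER` categories, so a "Cell culture" subsection under "Methods" is
retrievable as `METHODS`. Only with no categorised ancestor does a
section become `OTHER`. Tagging is total (every section of a parseable
article gets a non-empty set) and a pure function of the document and
ruleset.

The shipped ruleset (`rules/default.yaml`) carries the conclusion rule's
seven phrases verbatim and implementation-chosen canonical synonyms for
the other 15 categories. It is config, not code: any category→phrase-list
YAML can be substituted (`--rules`), with validation that codes are known,
lists are non-empty, and `OTHER` carries no rules.

## Evaluation conventions

The scoring unit is the (article, section, category) triple: multi-label
sections contribute one decision per category, so tagging a `METHODS`
section as `OTHER` costs one false negative (METHODS) *and* one false
positive (OTHER). Counts pool into micro-averaged precision, recall and
F (harmonic mean), reported as percentages rounded to two decimals;
per-category scores use the same convention. Zero denominators yield an
explicit undefined marker (`None`) rather than 0 or 100, so empty
fixtures cannot inflate scores. Gold files use the same line-delimited
JSON schema the tagger writes, so a manually corrected tag file is
directly usable as gold. Predicted articles absent from the gold are
ignored with a warning; gold rows that resolve to no predicted section
are an alignment error, not a silent false negative.

## Index and query semantics

Every token of a section is posted under each of the section's category
fields, plus `TITLE` and `ABSTRACT` pseudo-fields. Positions are
document-global token offsets shared across fields, with a gap of 100
between sections: a multi-category section therefore has *identical*
positions under each of its fields, and a phrase (consecutive positions
within one field) can never straddle a section boundary.

Query dialect: uppercase `AND`/`OR`/`NOT` (lowercase "and" is an ordinary
term), parentheses, `FIELD:term`, `FIELD:"quoted phrase"`,
`PUB_YEAR:<int>` (equality only — the only form the interface needs), and
bare terms/phrases for the default field. Adjacency is implicit `AND`;
precedence is NOT > AND > OR. Unknown field names and malformed syntax
raise distinct, named errors.

The default (unfielded) search matches across all fields but excludes
documents whose only matches lie in the `REF` field — the
references-only exclusion that keeps merely-citing articles out of
results. Three deliberate choices:

* the exclusion applies **per atomic unfielded clause**, not to the whole
  Boolean result, which is exactly what makes `mTOR OR REF:mTOR` mean
  "everything, including citation-only hits";
* an explicit `REF:` clause always bypasses the exclusion, and a global
  `--include-ref-only` switch disables it;
* `NOT` is permitted at top level and complements against the full
  indexed corpus (production engines often forbid bare negation; on a
  finite indexed set it is well defined, and De Morgan's laws hold
  exactly).

Results are unranked sets with sorted serialisation; relevance ranking is
out of scope. The index persists as a directory of plain JSON files with
a versioned manifest.

## Synthetic corpora

The generator emulates the one corpus-level property the statistics
modules depend on — a Zipfian heading inventory with a conventional head
and an idiosyncratic tail — plus the structural blocks the tagger keys
on. Headings are drawn i.i.d. from an exact Zipf(s) pmf over a
`vocab_size`-rank vocabulary (default 500, s = 1.0). The rare (tail)
ranks are assigned "custom" headings until their total probability mass
reaches `custom_fraction`; because mass is accumulated from the smallest
pmf values upward, the realised custom probability deviates from the
requested one by at most the pmf at the boundary rank (≈0.001 at the
defaults). Custom headings are verified at generation time to match no
rule, so their gold label `{OTHER}` is guaranteed, not probabilistic.
Head ranks hold cue phrases from the shipped ruleset plus suffix variants
("methods overview", …) verified to preserve exactly the base phrase's
category; their gold label is that category. With probability
`compound_fraction` a body heading joins two cue phrases of different
categories with " and ", gold = the union. Structural blocks (reference
list with citations, figure/table captions, acknowledgements, appendix,
keyword group, abstract) carry the gold their markup implies. Marker
tokens can be planted into sections of a chosen category (e.g. a term
that occurs only inside reference citations) to drive retrieval tests.

Generation is a pure function of the parameter set including the seed —
the same `GeneratorParams` yields byte-identical corpora — and gold paths
are derived by re-parsing the emitted XML, so they align with the
traversal by construction.

What the generator does **not** emulate: real prose (paragraphs are
filler sentences), publisher-specific XML quirks, nested body sections,
misspelled or truncated headings, citation networks, or non-XML
(scanned/PDF) content. Consequently, perfect rule recovery on clean
synthetic corpora shows that the matching machinery is sound and that
gold/tagger/evaluator compose correctly; it does not estimate precision
or recall on real archives, where heading phrasing is open-ended.

## Numerical and procedural choices

* Heading-frequency tables sort by descending count with lexicographic
  tie-break, making ranks (hence top-k mass and the Zipf fit)
  deterministic.
* The Zipf fit is OLS of log count on log rank over *all* ranks, with no
  truncation window; r² is the ordinary coefficient of determination,
  defined as 1 when the counts have zero variance (the constant fit is
  exact). At least 3 ranks are required.
* `top_k_mass` with k beyond the table length returns 1.0; k < 1 is an
  error.
* Category presence is binary per article (fraction of articles with ≥1
  section of the category), not a section count.
* Problem sizes: the test suite and the acceptance script use a
  200-article clean corpus for rule recovery, two corpora of ≤50
  documents with 200 random queries for index/brute-force equivalence,
  and an ~8,500-article corpus (≥50,000 heading draws over a 500-heading
  vocabulary) for Zipf-slope recovery — sizes at which the Monte-Carlo
  tolerances below are comfortably met while a full run stays in the
  seconds range.
* Tolerances: the fitted slope on a generated corpus is required to lie
  within ±0.15 of the generating exponent (Monte-Carlo variation across
  seeds is ~±0.03 at these sizes); closed-form checks (harmonic-number
  ratios, analytic fits) are asserted to 1e−9.

## Known limitations

* Rule coverage is the shipped synonym lists; headings outside them fall
  to `OTHER` by design ("Source data and the content of the database" is
  the canonical example). Swapping in a richer ruleset is a config
  change, not a code change.
* Plural-tolerance is suffix-`s` only; "appendices" and similar
  irregulars are handled by listing both forms in the config.
* The index is an in-memory dictionary structure serialised as JSON —
  appropriate for corpora up to the tens of thousands of documents used
  here, not a production-scale engine.
* Phrase queries do not support wildcards, slop, stemming or synonym
  expansion.
* The evaluator assumes gold files cover every section of the articles
  they annotate (which files produced by the tagged-record writer do);
  partially annotated articles would count unannotated predicted
  sections as false positives only if gold rows exist for that article.
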