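# sectiontag

Section-level tagging and section-scoped search for full-text scholarly
articles in JATS/NLM XML.

Most full-text search treats an article as one bag of words, so a query for
a protein retrieves articles that merely *cite* a paper about it, or mention
it once in the introduction. `sectiontag` is for text-mining and literature-
search engineers who want finer-grained retrieval: it classifies every
section of an article into one of 17 discourse-level categories from its
heading and XML structure, and builds a fielded index so queries can be
scoped to a section type — `METHODS:"mTOR"` finds articles that actually
*used* mTOR, `FIG:"protein structure"` finds relevant figure captions, and
the default unfielded search drops articles whose only hits sit in the
reference list.

## The method

**Categories.** Each section receives one or more codes from a fixed
inventory of 17: `INTRO, METHODS, RESULTS, DISCUSSION, CONCL, CASE, ACK,
AUTH_CON, COMP_INT, SUPPL, ABBR, KEYWORDS, REF, FIG, TABLE, APPENDIX` and
the fallback `OTHER`.

**Tagging.** The heading of each `<sec>` is normalised (case-folded,
enumeration prefixes like "1." / "IV." stripped, punctuation removed) and
matched against per-category cue-phrase rules such as the conclusion rule

```
conclusion | key message | future | summary | recommendation |
implications for clinical practice | concluding remark
```

A heading matching several categories ("Results and Discussion") is
assigned to **all** of them. Structural markup supplies categories where
headings don't: reference lists → `REF`, figure/table captions →
`FIG`/`TABLE`, acknowledgements → `ACK`, appendices → `APPENDIX`, keyword
groups → `KEYWORDS`. Unmatched subsections inherit their parent's
categories; anything left is `OTHER`. The rules live in an editable YAML
config (`src/sectiontag/rules/default.yaml`).

This works because section headings are heavily conventionalised: their
corpus-wide rank-frequency distribution follows Zipf's law
(count ∝ rank⁻ˢ), so a short list of cue phrases covers most of the mass.
`sectiontag.corpus_stats` measures exactly this (top-k heading mass,
fitted log-log slope) on any corpus.

**Scoring.** Tagger output is scored against gold annotations at the
(article, section, category) level with per-category and micro-averaged
precision/recall/F. As a consistency check on that arithmetic: a tagger
measured at P = 99.84% and R = 96.27% has F = 2PR/(P+R) = 98.02%.

**Search.** `sectiontag.section_index` posts every token under each of its
section's category fields (plus `TITLE`/`ABSTRACT`) with positional
postings, and evaluates a Boolean dialect: `AND`/`OR`/`NOT`, parentheses,
quoted phrases, `FIELD:term` scoping and `PUB_YEAR:2012` filters.

**Synthetic corpora.** Real open-access corpora are too large to ship, so
`sectiontag.fixtures` generates deterministic JATS corpora with gold
labels: headings drawn from an exactly Zipf-distributed vocabulary whose
head is cue phrases (gold = the rule's category) and whose tail is
verified-unmatchable "custom" headings (gold = `OTHER`).

## Worked example

```python
import sectiontag as st

doc = st.parse_article(xml_text)      # a JATS article (string or bytes)
tagged = st.tag_article(doc)
for s in tagged.sections:
    print(f"{list(s.path)}  {s.heading_raw!r:55} -> {sorted(s.categories)}")

index = st.build_index([(doc, tagged)])
print("search 'mTOR'     ->", st.search(index, "mTOR"))
print("search 'REF:mTOR' ->", st.search(index, "REF:mTOR"))
```

For an article with an introduction, a section titled "Source data and the
content of the database", a combined results/discussion section and a
reference list citing an mTOR paper, this prints:

```
[0]  'Introduction'                                          -> ['INTRO']
[1]  'Source data and the content of the database'           -> ['OTHER']
[2]  'Results and Discussion'                                -> ['DISCUSSION', 'RESULTS']
[3]  'References'                                            -> ['REF']
search 'mTOR'     -> ['PMC1347389']
search 'REF:mTOR' -> ['PMC1347389']
```

Line by line: the IMRAD headings match their cue phrases; the idiosyncratic
"Source data …" heading matches no rule and falls back to `OTHER`; the
compound heading gets both codes; the reference list is tagged
structurally. The article also contains "mTOR" in its body, so the default
search returns it — had "mTOR" occurred *only* in the references, `mTOR`
would return nothing while `REF:mTOR` still would.

The same pipeline is available from the shell:

```bash
sectiontag gen -o corpus --n 100 --seed 42        # synthetic JATS corpus + gold
sectiontag tag corpus -o tagged.jsonl             # tag every article
sectiontag eval tagged.jsonl corpus/gold.jsonl    # micro P/R/F vs gold
sectiontag stats corpus --top-k 150               # heading Zipf diagnostics
sectiontag index corpus -o idx
sectiontag search idx '(METHODS:"mTOR") AND PUB_YEAR:2012'
```

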