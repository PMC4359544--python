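import pytest

import sectiontag as st


def article_xml(
    article_id: str = "PMC0000001",
    year: int | None = 2012,
    body=(("Methods", "mTOR signalling assay"),),
    refs=(),
    figs=(),
    tables=(),
    ack: str | None = None,
    abstract: str | None = None,
    kwds=(),
) -> str:
    """Assemble a minimal JATS article for tests."""
    parts = ['<article article-type="research-article">', "<front><article-meta>"]
    parts.append(f'<article-id pub-id-type="pmcid">{article_id}</article-id>')
    parts.append("<title-group><article-title>Test article</article-title></title-group>")
    if year is not None:
        parts.append(f"<pub-date><year>{year}</year></pub-date>")
    if abstract is not None:
        parts.append(f"<abstract><p>{abstract}</p></abstract>")
    if kwds:
        parts.append(
            "<kwd-group>" + "".join(f"<kwd>{k}</kwd>" for k in kwds) + "</kwd-group>"
        )
    parts.append("</article-meta></front>")
    parts.append("<body>")
    for heading, text in body:
        if isinstance(text, (list, tuple)):  # nested: (heading, [(child, text), ...])
            inner = "".join(
                f"<sec><title>{ch}</title><p>{ct}</p></sec>" for ch, ct in text
            )
            parts.append(f"<sec><title>{heading}</title>{inner}</sec>")
        else:
            parts.append(f"<sec><title>{heading}</title><p>{text}</p></sec>")
    for caption in figs:
        parts.append(f"<fig><caption><p>{caption}</p></caption></fig>")
    for caption in tables:
        parts.append(f"<table-wrap><caption><p>{caption}</p></caption></table-wrap>")
    parts.append("</body>")
    back = []
    if ack is not None:
        back.append(f"<ack><title>Acknowledgements</title><p>{ack}</p></ack>")
    if refs:
        citations = "".join(
            f"<ref><mixed-citation>{c}</mixed-citation></ref>" for c in refs
        )
        back.append(f"<ref-list><title>References</title>{citations}</ref-list>")
    if back:
        parts.append("<back>" + "".join(back) + "</back>")
    parts.append("</article>")
    return "".join(parts)


@pytest.fixture(scope="session")
def ruleset():
    return st.default_ruleset()


@pytest.fixture()
def mtor_corpus():
    """Two-document corpus: D1 has mTOR in Methods (2012), D2 only cites it."""
    d1 = st.parse_article(
        article_xml("D1", 2012, body=(("Methods", "mTOR signalling assay"),))
    )
    d2 = st.parse_article(
        article_xml(
            "D2",
            2013,
            body=(("Introduction", "background on kinases"),),
            refs=("Smith J. mTOR signalling review. 2010.",),
        )
    )
    return [(d, st.tag_article(d)) for d in (d1, d2)]


@pytest.fixture()
def mtor_index(mtor_corpus):
    return st.build_index(mtor_corpus)
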