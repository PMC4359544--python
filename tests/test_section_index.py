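import numpy as np
import pytest

import sectiontag as st
from sectiontag.section_index import (
    Bool,
    IndexingError,
    Phrase,
    QueryFieldError,
    QuerySyntaxError,
    Term,
    YearEq,
    build_index,
    execute,
    parse_query,
    tokenize,
)

from conftest import article_xml
from oracle import corpus_vocabulary, naive_execute, random_query_string


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("mTOR signalling", ["mtor", "signalling"]),
            ("protein structure.", ["protein", "structure"]),
            ("", []),
            ("mTOR-dependent", ["mtor", "dependent"]),
            ("IL-2/IL-4 at 37C", ["il", "2", "il", "4", "at", "37c"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected


class TestBuildIndex:
    def test_tokens_posted_under_section_category(self, mtor_index):
        assert "D1" in mtor_index.docs_with_term("mtor", "METHODS")

    def test_ref_only_doc_posts_only_under_ref(self, mtor_index):
        fields = {
            f
            for f in st.FIELD_CODES
            if "D2" in mtor_index.docs_with_term("mtor", f)
        }
        assert fields == {"REF"}

    def test_multicategory_section_shares_positions(self):
        doc = st.parse_article(
            article_xml("D3", body=(("Results and Discussion", "the assay worked"),))
        )
        idx = build_index([(doc, st.tag_article(doc))])
        res = idx.postings["assay"]["RESULTS"]["D3"]
        dis = idx.postings["assay"]["DISCUSSION"]["D3"]
        assert res == dis

    def test_duplicate_doc_id_rejected(self, mtor_corpus):
        doc, tagged = mtor_corpus[0]
        with pytest.raises(IndexingError):
            build_index([(doc, tagged), (doc, tagged)])

    def test_pub_year_in_meta(self, mtor_index):
        assert mtor_index.doc_meta["D1"]["pub_year"] == 2012

    def test_any_field_union(self, mtor_index):
        assert mtor_index.docs_any_field_term("mtor") == {"D1", "D2"}

    def test_persistence_round_trip(self, mtor_index, tmp_path):
        mtor_index.save(tmp_path / "idx")
        loaded = st.FieldedIndex.load(tmp_path / "idx")
        assert loaded.postings == {
            t: {f: dict(d) for f, d in fields.items()}
            for t, fields in mtor_index.postings.items()
        }
        assert st.search(loaded, "mTOR") == ["D1"]


class TestParseQuery:
    def test_default_or_ref(self):
        assert parse_query("mTOR OR REF:mTOR") == Bool(
            "OR", (Term(None, "mtor"), Term("REF", "mtor"))
        )

    def test_fielded_phrase_and_year(self):
        assert parse_query('(METHODS:"mTOR") AND PUB_YEAR:2012') == Bool(
            "AND", (Phrase("METHODS", ("mtor",)), YearEq(2012))
        )

    def test_fig_phrase(self):
        assert parse_query('FIG:"protein structure"') == Phrase(
            "FIG", ("protein", "structure")
        )

    def test_precedence_not_and_or(self):
        ast = parse_query("a OR NOT b AND c")
        assert ast == Bool(
            "OR",
            (
                Term(None, "a"),
                Bool("AND", (Bool("NOT", (Term(None, "b"),)), Term(None, "c"))),
            ),
        )

    def test_adjacency_is_implicit_and(self):
        assert parse_query("mtor kinase") == Bool(
            "AND", (Term(None, "mtor"), Term(None, "kinase"))
        )

    def test_lowercase_and_is_a_term(self):
        assert parse_query("salt and pepper") == Bool(
            "AND",
            (Term(None, "salt"), Term(None, "and"), Term(None, "pepper")),
        )

    @pytest.mark.parametrize("bad", ["", "   ", "(a OR b", "a)", '"unclosed', 'a ""'])
    def test_syntax_errors(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)

    def test_unknown_field_named_in_error(self):
        with pytest.raises(QueryFieldError, match="BODYTEXT"):
            parse_query("BODYTEXT:mtor")

    def test_pub_year_requires_integer(self):
        with pytest.raises(QuerySyntaxError):
            parse_query("PUB_YEAR:abc")


class TestExecute:
    def test_default_excludes_references_only(self, mtor_index):
        assert st.search(mtor_index, "mTOR") == ["D1"]

    def test_explicit_ref_clause_bypasses_exclusion(self, mtor_index):
        assert st.search(mtor_index, "mTOR OR REF:mTOR") == ["D1", "D2"]

    def test_methods_phrase_with_year_filter(self, mtor_index):
        assert st.search(mtor_index, '(METHODS:"mTOR") AND PUB_YEAR:2012') == ["D1"]

    def test_include_ref_only_flag_disables_exclusion(self, mtor_index):
        assert st.search(mtor_index, "mTOR", include_ref_only=True) == ["D1", "D2"]

    def test_not_complements_against_corpus(self, mtor_index):
        assert st.search(mtor_index, "NOT mTOR") == ["D2"]
        assert st.search(mtor_index, "NOT REF:mTOR") == ["D1"]

    def test_default_union_with_ref_equals_any(self, mtor_index):
        default = execute(mtor_index, parse_query("mTOR"))
        ref = execute(mtor_index, parse_query("REF:mTOR"))
        assert default | ref == mtor_index.docs_any_field_term("mtor")

    def test_phrase_does_not_cross_section_boundary(self):
        doc = st.parse_article(
            article_xml(
                "D4",
                body=(
                    ("Results", "the kinase assay ends with alpha"),
                    ("Discussion", "beta starts this section"),
                ),
            )
        )
        idx = build_index([(doc, st.tag_article(doc))])
        # "alpha beta" spans the two sections: adjacent in reading order
        # but never inside one section, so the phrase must not match
        assert execute(idx, parse_query('"alpha beta"')) == set()
        assert execute(idx, parse_query('"kinase assay"')) == {"D4"}

    def test_phrase_subset_of_conjunction(self, mtor_corpus, mtor_index):
        phrase = execute(mtor_index, parse_query('METHODS:"mtor signalling"'))
        conj = execute(
            mtor_index, parse_query("METHODS:mtor AND METHODS:signalling")
        )
        assert phrase <= conj


class TestBruteForceEquivalence:
    def test_random_queries_agree_with_naive_scan(self):
        """On a generated corpus the index must agree exactly with a scan
        that re-reads every document for every query; De Morgan and the
        phrase-subset law hold on every trial."""
        params = st.GeneratorParams(
            n_articles=30,
            custom_fraction=0.2,
            compound_fraction=0.1,
            include_structural=("ref", "fig", "table", "ack", "kwd"),
            marker_tokens=(("refonlyterm", "REF"), ("methodsterm", "METHODS")),
            seed=17,
        )
        corpus = [(doc, st.tag_article(doc)) for doc, _ in st.gen_documents(params)]
        index = build_index(corpus)
        vocab = corpus_vocabulary(corpus)
        years = sorted({doc.pub_year for doc, _ in corpus})
        rng = np.random.default_rng(23)

        for _ in range(60):
            query = random_query_string(rng, vocab, years)
            ast = parse_query(query)
            assert execute(index, ast) == naive_execute(corpus, ast), query

        # De Morgan over random conjunctions
        for _ in range(20):
            a = vocab[int(rng.integers(len(vocab)))]
            b = vocab[int(rng.integers(len(vocab)))]
            lhs = execute(index, parse_query(f"NOT ({a} AND {b})"))
            rhs = execute(index, parse_query(f"NOT {a} OR NOT {b}"))
            assert lhs == rhs
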