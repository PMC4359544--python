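import itertools

import pytest
from hypothesis import given, settings, strategies as hyp_st

import sectiontag as st
from sectiontag.jats_io import SectionNode, StructuralHint
from sectiontag.section_tagger import RuleConfigError

from conftest import article_xml


class TestNormalizeHeading:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("1. METHODS:", "methods"),
            ("Materials and Methods", "materials and methods"),
            ("", ""),
            ("2.3 Statistical analysis.", "statistical analysis"),
            ("IV. Discussion", "discussion"),
            ("  Results   and \t Discussion ", "results and discussion"),
            ("Conclusion & Future Work", "conclusion & future work"),
            ("Methods—overview", "methods overview"),
        ],
    )
    def test_examples(self, raw, expected):
        assert st.normalize_heading(raw) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hyp_st.text(max_size=60))
    def test_idempotent(self, text):
        once = st.normalize_heading(text)
        assert st.normalize_heading(once) == once


class TestMatchCategories:
    @pytest.mark.parametrize(
        "heading, expected",
        [
            ("conclusion", {"CONCL"}),
            ("concluding remarks", {"CONCL"}),
            ("key messages", {"CONCL"}),
            ("implications for clinical practice", {"CONCL"}),
            ("results and discussion", {"RESULTS", "DISCUSSION"}),
            ("source data and the content of the database", set()),
            ("general discussion", {"DISCUSSION"}),
            ("discussant", set()),
            ("materials and methods", {"METHODS"}),
            ("acknowledgements", {"ACK"}),
            ("conflicts of interest", {"COMP_INT"}),
            ("", set()),
        ],
    )
    def test_examples(self, heading, expected, ruleset):
        assert st.match_categories(st.normalize_heading(heading), ruleset) == expected

    def test_word_bounding_blocks_substrings(self, ruleset):
        # "table" must not fire inside "vegetables"
        assert st.match_categories("eating vegetables", ruleset) == set()

    def test_union_over_all_singleton_pattern_pairs(self, ruleset):
        """Joining two single-category cue phrases with ' and ' yields the
        union of the two singleton category sets."""
        singletons = [
            (pattern, code)
            for pattern, code in ruleset.all_patterns()
            if st.match_categories(pattern, ruleset) == {code}
        ]
        assert singletons, "ruleset should contain single-category patterns"
        for (p1, c1), (p2, c2) in itertools.combinations(singletons, 2):
            joined = st.normalize_heading(f"{p1} and {p2}")
            assert st.match_categories(joined, ruleset) == {c1, c2}


class TestAssignStructural:
    @pytest.mark.parametrize(
        "hint, expected",
        [
            (StructuralHint.REF_LIST, {"REF"}),
            (StructuralHint.FIG_CAPTION, {"FIG"}),
            (StructuralHint.TABLE_CAPTION, {"TABLE"}),
            (StructuralHint.ACK_BLOCK, {"ACK"}),
            (StructuralHint.APP_BLOCK, {"APPENDIX"}),
            (StructuralHint.KWD_GROUP, {"KEYWORDS"}),
            (StructuralHint.ABSTRACT_BLOCK, {"OTHER"}),
            (StructuralHint.BODY_SEC, set()),
            (StructuralHint.NONE, set()),
        ],
    )
    def test_mapping(self, hint, expected):
        assert st.assign_structural(SectionNode(structural_hint=hint)) == expected


class TestTagArticle:
    def test_imrad_headings(self):
        doc = st.parse_article(
            article_xml(
                body=(
                    ("Introduction", "a"),
                    ("Methods", "b"),
                    ("Results", "c"),
                    ("Discussion", "d"),
                )
            )
        )
        tagged = st.tag_article(doc)
        assert {"INTRO", "METHODS", "RESULTS", "DISCUSSION"} <= tagged.present_categories

    def test_unmatchable_heading_falls_back_to_other(self):
        doc = st.parse_article(
            article_xml(body=(("Source data and the content of the database", "x"),))
        )
        tagged = st.tag_article(doc)
        assert tagged.sections[0].categories == frozenset({"OTHER"})

    def test_structural_only_article(self):
        doc = st.parse_article(article_xml(body=(), refs=("c1",)))
        tagged = st.tag_article(doc)
        assert [s.categories for s in tagged.sections] == [frozenset({"REF"})]

    def test_subsection_inherits_parent_categories(self):
        doc = st.parse_article(
            article_xml(body=(("Methods", [("Cell culture", "hela")]),))
        )
        tagged = st.tag_article(doc)
        by_path = {s.path: s.categories for s in tagged.sections}
        assert by_path[(0,)] == frozenset({"METHODS"})
        assert by_path[(0, 0)] == frozenset({"METHODS"})

    def test_child_under_other_parent_stays_other(self):
        doc = st.parse_article(
            article_xml(body=(("Curated registry outlook", [("More topics", "x")]),))
        )
        tagged = st.tag_article(doc)
        for section in tagged.sections:
            assert section.categories == frozenset({"OTHER"})

    def test_totality_and_determinism(self):
        xml = article_xml(
            body=(("Whatever heading", "x"), ("Results", "y")),
            refs=("c",),
            figs=("f",),
            abstract="abs",
        )
        doc = st.parse_article(xml)
        first = st.tag_article(doc)
        second = st.tag_article(st.parse_article(xml))
        assert all(s.categories for s in first.sections)
        assert [(s.path, s.categories) for s in first.sections] == [
            (s.path, s.categories) for s in second.sections
        ]

    def test_present_categories_is_union(self):
        doc = st.parse_article(article_xml(refs=("c",), abstract="abs"))
        tagged = st.tag_article(doc)
        union = frozenset().union(*(s.categories for s in tagged.sections))
        assert tagged.present_categories == union


class TestRuleSetLoading:
    def test_default_has_16_rules_and_no_other(self, ruleset):
        assert len(ruleset.rules) == 16
        assert "OTHER" not in ruleset.rules
        assert set(ruleset.rules) == set(st.CATEGORY_CODES) - {"OTHER"}

    def test_exactly_17_category_codes(self):
        assert len(st.CATEGORY_CODES) == 17
        assert len(set(st.CATEGORY_CODES)) == 17
        assert "OTHER" in st.CATEGORY_CODES
        assert len(st.SectionCategory) == 17

    def test_other_rule_rejected(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("OTHER:\n  - misc\n")
        with pytest.raises(RuleConfigError):
            st.load_ruleset(cfg)

    def test_unknown_code_rejected(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("BOGUS:\n  - misc\n")
        with pytest.raises(RuleConfigError, match="BOGUS"):
            st.load_ruleset(cfg)

    def test_empty_pattern_list_rejected(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("CONCL: []\n")
        with pytest.raises(RuleConfigError):
            st.load_ruleset(cfg)

    def test_custom_ruleset_loadable(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("CONCL:\n  - conclusion\n  - concluding remark\n")
        rs = st.load_ruleset(cfg)
        assert st.match_categories("concluding remarks", rs) == {"CONCL"}
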