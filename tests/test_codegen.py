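"""XPath compilation: label wrapping, proximity regexes, boolean mapping."""

import re

import numpy as np
import pytest

from soxpath import (
    And, CompositeTerm, ConceptRef, Not, Or, PatternError, SearchConcept,
    SearchModel, SearchQuery, SimpleTerm, TermLabel, annotate_model,
    compile_label, compile_model, compile_query, evaluate_query, load_model,
)
from soxpath.codegen import composite_alternatives, compile_simple_term
from soxpath.randgen import random_corpus, random_model


class TestCompileLabel:
    @pytest.mark.parametrize("text,expected", [
        ("eine floride Entzündung", True),
        ("mehrere florides Infiltrate", True),
        ("nonfloride Anteile", False),       # left boundary
        ("floridexx", True),                  # (\w)* absorbs the suffix
    ])
    def test_stem_pattern_matches_inflections_not_compounds(self, text, expected):
        rx = compile_label(TermLabel(r"florid(\w)*"))
        assert (re.search(rx, text) is not None) is expected

    @pytest.mark.parametrize("text,expected", [
        ("2 cm breit", True), ("bcm", False), ("cmx", False), ("(cm)", True),
    ])
    def test_whole_word_boundaries(self, text, expected):
        rx = compile_label(TermLabel("cm"))
        assert (re.search(rx, text) is not None) is expected

    def test_umlauts_count_as_word_characters(self):
        rx = compile_label(TermLabel("Span"))
        assert re.search(rx, "Prostataspäne") is None
        assert re.search(rx, "ein Span davon") is not None

    def test_case_folding_via_flag_group(self):
        rx = compile_label(TermLabel("uterus", case_sensitive=False))
        assert re.search(rx, "im Uterus gelegen")
        assert "(?i:" in rx

    def test_empty_pattern_rejected(self):
        with pytest.raises(PatternError):
            compile_label(TermLabel(""))

    @pytest.mark.parametrize("pattern", [r"(?=x)y", r"(x)\1", r"(?i)x", r"\bx"])
    def test_dialect_divergent_constructs_rejected(self, pattern):
        with pytest.raises(PatternError):
            compile_label(TermLabel(pattern))


def two_section_model(**composites) -> SearchModel:
    from soxpath import build_structure
    root = build_structure({
        "name": "pehr", "namespace": "urn:b",
        "children": [{"name": "content", "namespace": "urn:b", "children": [
            {"name": "Overall_interpretation", "namespace": "urn:i"},
            {"name": "Macroscopy", "namespace": "urn:f"},
        ]}]})
    m = SearchModel(structure=root)
    m.simple_terms["adeno"] = SimpleTerm("adeno", (TermLabel(r"Adenokarzinom(\w)*"),))
    m.simple_terms["leio"] = SimpleTerm("leio", (TermLabel(r"Leiomyom(\w)*"),))
    m.simple_terms["cm"] = SimpleTerm("cm", (TermLabel("cm"),))
    for cid, spec in composites.items():
        m.composite_terms[cid] = spec
    return m


class TestSimpleTerm:
    #: six interpretation texts and whether the adenocarcinoma stem occurs
    DOCS = [
        ("d0", "ein Adenokarzinom liegt vor", True),
        ("d1", "mehrere Adenokarzinome nachweisbar", True),
        ("d2", "kein Anhalt für Malignität", False),
        ("d3", "Pseudoadenokarzinom artige Struktur", False),
        ("d4", "Adenokarzinoms Randsaum", True),
        ("d5", "", False),
    ]

    def test_predicate_selects_exactly_regex_scan_of_section(self, corpus_builder):
        """Compiled predicate agrees with a direct regex scan of the
        extracted section text on a hand-built six-document corpus."""
        m = two_section_model()
        m.concepts["c"] = SearchConcept("c", "adeno", "Overall_interpretation")
        m.queries["q"] = SearchQuery("q", ConceptRef("c"))
        builder = corpus_builder(m)
        for doc_id, text, _ in self.DOCS:
            builder.add(doc_id, Overall_interpretation=text)
        result = evaluate_query(builder.open(), compile_query(m.queries["q"], m))
        expected = sorted(d for d, text, _ in self.DOCS
                          if re.search(r"(?<!\w)Adenokarzinom(\w)*(?!\w)", text))
        assert result.matches == expected
        assert result.matches == [d for d, _t, hit in self.DOCS if hit]

    def test_one_disjunct_per_label(self):
        m = two_section_model()
        term = SimpleTerm("t", (TermLabel("aaa"), TermLabel("bbb")))
        pred = compile_simple_term(term, m.node_by_id("Macroscopy"), m)
        assert pred.xpath_fragment.count("matches(") == 2

    def test_document_without_section_never_matches(self, corpus_builder):
        m = two_section_model()
        m.concepts["c"] = SearchConcept("c", "adeno", "Overall_interpretation")
        m.queries["q"] = SearchQuery("q", ConceptRef("c"))
        builder = corpus_builder(m)
        builder.root.joinpath("bare.xml").write_bytes(
            b'<pehr xmlns="urn:b"><content/></pehr>')
        result = evaluate_query(builder.open(), compile_query(m.queries["q"], m))
        assert result.matches == []


class TestCompositeTerm:
    def test_cross_product_counts_alternatives(self):
        m = two_section_model()
        m.simple_terms["x"] = SimpleTerm("x", (TermLabel("x1"), TermLabel("x2")))
        m.simple_terms["y"] = SimpleTerm("y", (TermLabel("y1"), TermLabel("y2"),
                                               TermLabel("y3")))
        unordered = CompositeTerm("u", ("x", "y"), max_distance=1, ordered=False)
        ordered = CompositeTerm("o", ("x", "y"), max_distance=1, ordered=True)
        assert len(composite_alternatives(unordered, m)) == 12  # 2*3 tuples * 2 orders
        assert len(composite_alternatives(ordered, m)) == 6

    @pytest.mark.parametrize("text,distance,expected", [
        ("Leiomyom von 2 cm Größe", 2, True),
        ("Leiomyom im Fundus, Abstand 2 cm", 2, False),  # >= 3 intervening words
        ("2 cm großes Leiomyom", 2, True),               # reversed order
        ("Leiomyom cm", 0, True),                        # immediate adjacency
        ("Leiomyom von cm", 0, False),
    ])
    def test_word_distance_semantics(self, corpus_builder, text, distance, expected):
        comp = CompositeTerm("lc", ("leio", "cm"), max_distance=distance)
        m = two_section_model(lc=comp)
        m.concepts["c"] = SearchConcept("c", "lc", "Overall_interpretation")
        m.queries["q"] = SearchQuery("q", ConceptRef("c"))
        builder = corpus_builder(m)
        builder.add("d", Overall_interpretation=text)
        result = evaluate_query(builder.open(), compile_query(m.queries["q"], m))
        assert (result.matches == ["d"]) is expected


class TestCompileQuery:
    def test_q1_expression_shape(self, q1_native):
        xpath = compile_query(q1_native.queries["Q1"], q1_native).xpath
        assert xpath.count("not(") == 1
        assert " and " in xpath and " or " in xpath
        assert xpath.startswith("/ns1:pehr[")

    def test_single_concept_query_is_wrapped_predicate(self):
        m = two_section_model()
        m.concepts["c"] = SearchConcept("c", "adeno", "Overall_interpretation")
        m.queries["q"] = SearchQuery("q", ConceptRef("c"))
        cq = compile_query(m.queries["q"], m)
        frag = compile_simple_term(m.simple_terms["adeno"],
                                   m.node_by_id("Overall_interpretation"), m).xpath_fragment
        assert cq.xpath == f"/ns1:pehr[{frag}]"

    def test_compilation_is_deterministic(self, pathology_model):
        first = {q: c.xpath for q, c in compile_model(pathology_model).items()}
        second = {q: c.xpath for q, c in compile_model(pathology_model).items()}
        assert first == second

    def test_every_used_prefix_is_declared(self, pathology_model):
        for cq in compile_model(pathology_model).values():
            for prefix in set(re.findall(r"(?<![\w:])(\w+):", cq.xpath)):
                if prefix not in ("urn",):
                    assert prefix in cq.prefix_map


class TestBooleanAlgebra:
    def _result_sets(self, model, exprs, corpus):
        out = []
        for i, expr in enumerate(exprs):
            q = SearchQuery(f"tmp{i}", expr)
            model.queries[q.id] = q
            out.append(evaluate_query(corpus, compile_query(q, model)).matches)
            del model.queries[q.id]
        return out

    def test_double_negation_and_de_morgan_preserve_results(self, tmp_path):
        rng = np.random.default_rng(99)
        m = random_model(rng)
        random_corpus(rng, m, tmp_path / "c", n_docs=40)
        from soxpath import open_corpus
        corpus = open_corpus(tmp_path / "c")
        cids = list(m.concepts)
        a, b = ConceptRef(cids[0]), ConceptRef(cids[-1])
        pairs = [
            (a, Not(Not(a))),
            (Not(And((a, b))), Or((Not(a), Not(b)))),
            (Not(Or((a, b))), And((Not(a), Not(b)))),
        ]
        for left, right in pairs:
            lres, rres = self._result_sets(m, [left, right], corpus)
            assert lres == rres

    def test_monotonicity_in_distance_and_labels(self, corpus_builder):
        """Growing max_distance, or adding a label to a positive term, never
        shrinks the result set."""
        texts = ["Leiomyom von zwei drei vier cm", "Leiomyom cm", "Leiomyom allein",
                 "cm ohne Bezug", "Leiomyom a b c d e cm"]
        prev: set = set()
        for d in (0, 1, 3, 6):
            comp = CompositeTerm("lc", ("leio", "cm"), max_distance=d)
            m = two_section_model(lc=comp)
            m.concepts["c"] = SearchConcept("c", "lc", "Overall_interpretation")
            m.queries["q"] = SearchQuery("q", ConceptRef("c"))
            builder = corpus_builder(m, subdir=f"d{d}")
            for i, t in enumerate(texts):
                builder.add(f"d{i}", Overall_interpretation=t)
            got = set(evaluate_query(builder.open(), compile_query(m.queries["q"], m)).matches)
            assert got >= prev
            prev = got

        base = two_section_model()
        base.concepts["c"] = SearchConcept("c", "adeno", "Overall_interpretation")
        base.queries["q"] = SearchQuery("q", ConceptRef("c"))
        builder = corpus_builder(base, subdir="labels")
        builder.add("d0", Overall_interpretation="Adenokarzinom")
        builder.add("d1", Overall_interpretation="Plattenepithelkarzinom")
        small = set(evaluate_query(builder.open(), compile_query(base.queries["q"], base)).matches)
        base.simple_terms["adeno"] = SimpleTerm(
            "adeno", (TermLabel(r"Adenokarzinom(\w)*"), TermLabel(r"Plattenepithelkarzinom")))
        big = set(evaluate_query(builder.open(), compile_query(base.queries["q"], base)).matches)
        assert big >= small and big == {"d0", "d1"}


def test_annotation_round_trip_preserves_xpaths(pathology_model, tmp_path):
    compiled = compile_model(pathology_model)
    out = tmp_path / "annotated.yaml"
    annotate_model(pathology_model, list(compiled.values()), out)
    reloaded = load_model(out)
    assert len([q for q in reloaded.queries.values() if q.xpath_annotation]) == 7
    for qid, cq in compiled.items():
        assert reloaded.queries[qid].xpath_annotation == cq.xpath
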