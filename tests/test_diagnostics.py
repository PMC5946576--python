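"""Enumeration alignment, quantity extraction and summarization."""

import numpy as np
import pytest
from scipy import stats

from soxpath import (
    ConceptRef, And, SearchConcept, SearchQuery, SimpleTerm, TermLabel,
    compile_query, enum_alignment_report, evaluate_query, extract_quantities,
    fetch_snippets, summarize_quantities,
)
from soxpath.diagnostics import enumeration_items, ordinal_at
from soxpath.engine import SnippetRecord
from soxpath.synth import QuantityPlan, realize_quantity
from tests.conftest import enumerated_text


class TestEnumerationParsing:
    def test_item_markers_and_ordinals(self):
        text = "1. erster Punkt 2. zweiter Punkt 12) zwölfter Punkt"
        items = enumeration_items(text)
        assert [o for o, _ in items] == [1, 2, 12]
        assert ordinal_at(text.index("erster"), items) == 1
        assert ordinal_at(text.index("zwölfter"), items) == 12
        assert ordinal_at(0, items) == 1

    def test_numbers_inside_measurements_are_not_markers(self):
        assert enumeration_items("Gewicht 18,3 g und 2 cm") == []

    def test_preamble_before_first_marker_has_no_ordinal(self):
        text = "Vorbemerkung 1. Punkt"
        assert ordinal_at(0, enumeration_items(text)) is None


def snippet(doc, concept, text, spans):
    return SnippetRecord(doc_id=doc, query_id="q", concept_id=concept,
                         section_path=[("urn:x", "sec")], section_index=1,
                         text=text, matched_spans=spans)


def spans_of(text, needle, pattern="p"):
    i = text.index(needle)
    return [(pattern, i, i + len(needle))]


class TestAlignment:
    def _report(self, records, pathology_model):
        return enum_alignment_report(records, pathology_model)

    def test_same_item_is_aligned(self, pathology_model):
        mat = enumerated_text({13: "Prostatamaterial 18,3 g"}, 14)
        interp = enumerated_text({13: "Adenokarzinom nachweisbar"}, 14)
        recs = [snippet("d", "g_unit_in_macro", mat, spans_of(mat, "g", "g")),
                snippet("d", "adeno_in_interp", interp,
                        spans_of(interp, "Adenokarzinom"))]
        (report,) = self._report(recs, pathology_model)
        assert report.aligned is True
        assert report.item_indices == {"adeno_in_interp": [13], "g_unit_in_macro": [13]}

    def test_weight_in_item_13_without_adenocarcinoma_there_is_flagged(self, pathology_model):
        """The narrated prostate case: the flake weight sits in the 13th
        item while the adenocarcinoma match does not."""
        mat = enumerated_text({13: "Prostatamaterial 18,3 g"}, 14)
        interp = enumerated_text({5: "Adenokarzinom nachweisbar"}, 14)
        recs = [snippet("d", "g_unit_in_macro", mat, spans_of(mat, "g", "g")),
                snippet("d", "adeno_in_interp", interp,
                        spans_of(interp, "Adenokarzinom"))]
        (report,) = self._report(recs, pathology_model)
        assert report.aligned is False

    def test_leiomyoma_item_11_uterus_item_15_is_flagged(self, pathology_model):
        """The narrated uterus case: 'Leiomyom' in the 11th interpretation
        item but 'Uterus' in the 15th specimen item."""
        interp = enumerated_text({11: "Leiomyom von 2 cm"}, 16)
        mat = enumerated_text({15: "Uterus Anteile"}, 16)
        recs = [snippet("d", "leiomyoma_in_interp", interp, spans_of(interp, "Leiomyom")),
                snippet("d", "uterus_in_material", mat, spans_of(mat, "Uterus"))]
        (report,) = self._report(recs, pathology_model)
        assert report.aligned is False
        assert report.item_indices["leiomyoma_in_interp"] == [11]
        assert report.item_indices["uterus_in_material"] == [15]

    def test_non_enumerated_section_is_wildcard(self, pathology_model):
        interp = enumerated_text({3: "Adenokarzinom"}, 5)
        recs = [snippet("d", "adeno_in_interp", interp, spans_of(interp, "Adenokarzinom")),
                snippet("d", "g_unit_in_macro", "Gewicht 18,3 g", [("g", 13, 14)])]
        (report,) = self._report(recs, pathology_model)
        assert report.aligned is True

    def test_shared_ordinal_never_flagged_property(self, pathology_model):
        """Randomized: whenever all concepts share an ordinal, no flag."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            shared = int(rng.integers(1, 9))
            n = int(rng.integers(shared, 12)) + 1
            recs = []
            for cid in ("adeno_in_interp", "g_unit_in_macro", "uterus_in_material"):
                extra = int(rng.integers(1, n + 1))
                items = {shared: f"Treffer_{cid}"}
                if extra != shared:
                    items[extra] = f"Nebentreffer_{cid}"
                text = enumerated_text(items, n)
                spans = spans_of(text, f"Treffer_{cid}")
                if extra != shared and rng.random() < 0.5:
                    spans += spans_of(text, f"Nebentreffer_{cid}")
                recs.append(snippet("d", cid, text, spans))
            (report,) = self._report(recs, pathology_model)
            assert report.aligned is True


class TestQuantities:
    def test_min_and_max_weights_recovered(self):
        recs = [snippet("a", "c", "Gewicht 3 g eingesandt", []),
                snippet("b", "c", "Gewicht 38 g eingesandt", [])]
        values = [v for _d, v, _u in extract_quantities(recs, "g")]
        assert values == [3.0, 38.0]

    def test_decimal_comma_parsed(self):
        recs = [snippet("a", "c", "Durchmesser 2,5 cm", [])]
        assert extract_quantities(recs, "cm") == [("a", 2.5, "cm")]

    def test_proximity_filter_drops_unrelated_units(self, pathology_model):
        term = SimpleTerm("leio", (TermLabel(r"Leiomyom(\w)*"),))
        near = snippet("a", "c", "Leiomyom von 2 cm", [])
        far = snippet("b", "c", "Leiomyom im Fundus, weiter Abstand 2 cm", [])
        assert extract_quantities([near], "cm", term, 2) == [("a", 2.0, "cm")]
        assert extract_quantities([far], "cm", term, 2) == []

    def test_summary_statistics(self):
        s = summarize_quantities([3, 38], "g")
        assert (s.n, s.min, s.max, s.mean) == (2, 3.0, 38.0, 20.5)
        assert summarize_quantities([5], "g").sd == 0.0
        empty = summarize_quantities([], "g")
        assert empty.n == 0 and empty.mean is None and empty.sd is None

    def test_summary_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        vals = list(rng.normal(10, 2, 50))
        a = summarize_quantities(vals, "g")
        b = summarize_quantities(list(reversed(vals)), "g")
        assert (a.n, a.min, a.max) == (b.n, b.min, b.max)
        assert a.mean == pytest.approx(b.mean, rel=1e-12)
        assert a.sd == pytest.approx(b.sd, rel=1e-12)

    def test_seeded_sampler_recovers_clipped_normal_moments(self):
        """5000 seeded draws from the weight distribution match the
        closed-form moments of the zero-clipped normal within 3 SE."""
        mu, sigma = 18.26, 10.18
        rng = np.random.default_rng(5)
        plan = QuantityPlan(("normal", mu, sigma), "g", 1)
        vals = np.array([realize_quantity(plan, rng)[0] for _ in range(5000)])
        alpha = mu / sigma
        mean_clip = mu * stats.norm.cdf(alpha) + sigma * stats.norm.pdf(alpha)
        ex2 = (mu**2 + sigma**2) * stats.norm.cdf(alpha) \
            + mu * sigma * stats.norm.pdf(alpha)
        sd_clip = float(np.sqrt(ex2 - mean_clip**2))
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - mean_clip) < 3 * se
        assert abs(vals.std() - sd_clip) < 3 * sd_clip / np.sqrt(2 * len(vals))

    def test_uniform_support_and_adjacency(self):
        rng = np.random.default_rng(1)
        plan = QuantityPlan(("uniform", 2, 3), "cm", 0)
        for _ in range(200):
            value, tokens = realize_quantity(plan, rng)
            assert 2.0 <= value <= 3.0
            assert tokens[1] == "cm" and tokens[0].count(",") == 1
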