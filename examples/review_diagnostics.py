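"""Reviewer diagnostics: enumeration alignment and quantity summaries.

Builds a corpus where 30% of the positive documents have their two matches
planted in *different* enumeration items (a coreference false positive:
the weight belongs to a different specimen than the carcinoma finding).
The alignment report flags exactly those documents. A second corpus plants
gram weights from a normal distribution; extraction and summarization
recover its parameters.
"""

import tempfile

from soxpath import (
    And, ConceptRef, CorpusSpec, SearchQuery, TermPlan, compile_model,
    enum_alignment_report, extract_quantities, fetch_snippets,
    generate_corpus, summarize_quantities,
)
from soxpath.synth import QuantityPlan, bundled_model, default_term_plans

# --- enumeration alignment ------------------------------------------------
model = bundled_model()
model.queries["probe"] = SearchQuery(
    "probe", And((ConceptRef("adeno_in_interp"), ConceptRef("g_unit_in_macro"))))
plans = [p for p in default_term_plans()
         if p.concept_id in ("adeno_in_interp", "g_unit_in_macro")]

with tempfile.TemporaryDirectory() as td:
    corpus, manifest = generate_corpus(
        CorpusSpec(n_docs=150, seed=9, model=model, term_plans=plans,
                   enumeration_prob=1.0, misalignment_prob=0.3,
                   negation_prob=0.0), td)
    snippets = fetch_snippets(corpus, compile_model(model)["probe"], model, None)
    reports = enum_alignment_report(snippets, model)
    flagged = sorted(r.doc_id for r in reports if not r.aligned)
    injected = sorted(d for d, t in manifest.docs.items() if t.misaligned)
    print(f"retrieved documents reviewed: {len(reports)}")
    print(f"flagged as item-misaligned:   {len(flagged)} (injected: {len(injected)})")
    print(f"flags identical to injection: {flagged == injected}")
    example = next(r for r in reports if not r.aligned)
    print(f"example: {example.doc_id} -> {example.details}\n")

# --- quantity extraction --------------------------------------------------
model = bundled_model()
model.queries["weights"] = SearchQuery("weights", ConceptRef("g_unit_in_macro"))
plans = [TermPlan("g_unit_in_macro", ("Gewicht",), "Macroscopy", 1.0,
                  QuantityPlan(("normal", 18.26, 10.18), "g", 1))]

with tempfile.TemporaryDirectory() as td:
    corpus, _ = generate_corpus(
        CorpusSpec(n_docs=400, seed=13, model=model, term_plans=plans), td)
    snippets = fetch_snippets(corpus, compile_model(model)["weights"], model, None)
    values = [v for _d, v, _u in extract_quantities(snippets, "g")]
    s = summarize_quantities(values, "g")
    print(f"weights extracted: n={s.n}, min={s.min} g, max={s.max} g, "
          f"mean={s.mean:.2f} g, sd={s.sd:.2f} g")
    print("(generating distribution: normal(18.26, 10.18) clipped at 0)")
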