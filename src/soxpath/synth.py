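"""Synthetic section-structured pathology-record corpora with ground truth.

The generator emulates the phenomena that make section-scoped retrieval
interesting: documents split into Material / Macroscopy / Microscopy /
interpretation / staging sections (each section group in its own XML
namespace, including two ``value`` leaves that share a local name across
namespaces), enumerated item lists inside sections, German decimal-comma
quantities with unit tokens, a fixed negation phrase, and — on request —
the two false-positive mechanisms: matches of co-occurring concepts planted
in *different* enumeration items, and stray unit tokens unrelated to any
term.

Every planted fragment is checked against the active model's labels at
construction time, and filler vocabulary is screened the same way, so the
manifest's per-concept and per-query truth is exact by construction.
Identical spec + seed reproduce byte-identical corpora.
"""

from __future__ import annotations

import importlib.resources
import json
import os
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from lxml import etree

from .codegen import build_prefix_map
from .engine import CorpusHandle, open_corpus
from .io_native import loads_native, model_to_dict
from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, ModelError, Not, Or,
    SearchModel, SimpleTerm, StructureNode,
)
from .oracle import label_spans, _composite_spans
from .text import normalize


def bundled_model() -> SearchModel:
    """The packaged five-question pathology model (seven query variants)."""
    text = importlib.resources.files("soxpath.data").joinpath(
        "pathology_questions.yaml").read_text(encoding="utf-8")
    return loads_native(text)


def filler_vocabulary() -> list[str]:
    text = importlib.resources.files("soxpath.data").joinpath(
        "filler_de.txt").read_text(encoding="utf-8")
    return [w.strip() for w in text.splitlines()
            if w.strip() and not w.startswith("#")]


@dataclass(frozen=True)
class QuantityPlan:
    """A physical quantity attached to a planted term occurrence.

    ``distribution`` is ``("normal", mu, sigma)`` (truncated at 0 by
    clipping) or ``("uniform", a, b)``; the value is rendered with a German
    decimal comma at one decimal place, immediately followed by the unit
    token, the pair placed within ``attach_within`` tokens of the surface
    form.
    """

    distribution: tuple
    unit: str
    attach_within: int = 1


@dataclass(frozen=True)
class TermPlan:
    concept_id: str
    surface_forms: tuple[str, ...]
    section: str  # structure node id
    prevalence: float
    quantity: Optional[QuantityPlan] = None


#: The negation phrase planted by ``negation_prob`` (esophagus questions).
EXCLUSION_PHRASE = "ohne Nachweis einer Barrett-Schleimhaut"

#: Sections subject to enumeration-list formatting.
ENUMERABLE_SECTIONS = ("Material", "Macroscopy", "Overall_interpretation")


def default_term_plans() -> list[TermPlan]:
    """Plans matching the bundled model's concepts, with prevalences and the
    reported weight/size distributions as generator defaults."""
    return [
        TermPlan("g_unit_in_macro", ("Gewicht",), "Macroscopy", 0.55,
                 QuantityPlan(("normal", 18.26, 10.18), "g", 1)),
        TermPlan("blister_in_interp", ("Blister", "Blistern"), "Overall_interpretation", 0.12),
        TermPlan("adeno_in_interp", ("Adenokarzinom", "Adenokarzinome", "Adenokarzinoms"),
                 "Overall_interpretation", 0.35),
        TermPlan("c61_in_loc", ("C61",), "Localisation", 0.30),
        TermPlan("m8140_in_typ", ("M-8140/3",), "Typification", 0.28),
        TermPlan("k_no_rest_in_macro", ("ohne Rest", "ohne Reste"), "Macroscopy", 0.25),
        TermPlan("k_rest_in_macro", ("mit Rest",), "Macroscopy", 0.15),
        TermPlan("flake_in_macro", ("Prostataspäne", "Prostataspan"), "Macroscopy", 0.25),
        TermPlan("flake_in_interp", ("Prostataspäne",), "Overall_interpretation", 0.15),
        TermPlan("leiomyoma_in_interp", ("Leiomyom", "Leiomyome"), "Overall_interpretation",
                 0.20, QuantityPlan(("normal", 2.76, 1.42), "cm", 1)),
        TermPlan("uterus_in_material", ("Uterus",), "Material", 0.25),
        TermPlan("c18_in_loc", ("C18",), "Localisation", 0.20),
        TermPlan("colon_in_material", ("Colon", "Colonkarzinom"), "Material", 0.20),
        TermPlan("t2_in_staging", ("pT2", "pT2a"), "Overall_staging", 0.30),
        TermPlan("pn_in_staging", ("pN0", "pN1", "pN2"), "staging", 0.30),
        TermPlan("barrett_in_interp", ("Barrett-Schleimhaut",), "Overall_interpretation", 0.30),
        TermPlan("esophagus_in_material", ("Ösophagusbiopsie", "Ösophagusbiopsien"),
                 "Material", 0.25),
    ]


@dataclass
class CorpusSpec:
    """Study conditions of a synthetic corpus.

    Defaults: enumeration prevalence 0.64 (the fraction of records with
    enumerated content in the motivating audit), no misalignment or stray
    units (injections are opt-in), negation phrase in 15% of documents.
    """

    n_docs: int = 100
    seed: int = 0
    model: Optional[SearchModel] = None          # default: bundled_model()
    term_plans: Optional[list[TermPlan]] = None  # default: default_term_plans()
    enumeration_prob: float = 0.64
    misalignment_prob: float = 0.0
    stray_unit_prob: float = 0.0
    negation_prob: float = 0.15
    items_range: tuple[int, int] = (3, 6)

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ModelError("n_docs must be >= 1")
        for name in ("enumeration_prob", "misalignment_prob",
                     "stray_unit_prob", "negation_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ModelError(f"{name} must be in [0, 1], got {p}")


@dataclass
class PlantingRecord:
    concept_id: str
    section: str
    ordinal: Optional[int]
    surface: str
    value: Optional[float] = None
    stray: bool = False


@dataclass
class DocTruth:
    doc_id: str
    enumerated: bool
    misaligned: bool
    plantings: list[PlantingRecord] = field(default_factory=list)
    concepts: list[str] = field(default_factory=list)  # concepts matching


@dataclass
class GroundTruthManifest:
    docs: dict[str, DocTruth]
    queries: dict[str, list[str]]   # query id -> sorted positive doc ids
    concepts: dict[str, list[str]]  # concept id -> sorted doc ids

    def save(self, path: Union[str, os.PathLike]) -> None:
        payload = {
            "docs": {d: asdict(t) for d, t in self.docs.items()},
            "queries": self.queries,
            "concepts": self.concepts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1, sort_keys=True)


def realize_quantity(quantity: QuantityPlan, rng: np.random.Generator) \
        -> tuple[float, list[str]]:
    """Draw a value and render it as ``["<value>", "<unit>"]`` tokens.

    Normal draws are truncated at 0 by clipping; the value is rounded to one
    decimal (the rendered precision), and the returned float equals the
    rendered token, so manifests agree with what extraction can recover.
    """
    kind = quantity.distribution[0]
    if kind == "normal":
        _, mu, sigma = quantity.distribution
        raw = rng.normal(mu, sigma)
    elif kind == "uniform":
        _, a, b = quantity.distribution
        raw = rng.uniform(a, b)
    else:
        raise ModelError(f"unknown distribution {kind!r}")
    value = round(max(0.0, float(raw)), 1)
    rendered = f"{value:.1f}".replace(".", ",")
    return value, [rendered, quantity.unit]


# --- internal assembly ----------------------------------------------------

@dataclass
class _Fragment:
    tokens: list[str]
    plan_concept: Optional[str]  # the planting's nominal concept, if any
    surface: str
    value: Optional[float]
    stray: bool = False
    ordinal: Optional[int] = None


def _screen_filler(vocab: list[str], model: SearchModel) -> list[str]:
    """Drop filler words that any simple-term label could match."""
    labels = [lab for t in model.simple_terms.values() for lab in t.labels]
    out = []
    for word in vocab:
        if not any(label_spans(word, lab) for lab in labels):
            out.append(word)
    return out


def _fragment_concept_matches(fragment_text: str, section_ids: tuple[str, ...],
                              model: SearchModel) -> set[str]:
    """Concepts (bound to this section or its text-bearing leaf, simple
    terms) matching inside a planted fragment — the construction-time
    registration step."""
    hits: set[str] = set()
    for concept in model.concepts.values():
        if concept.node not in section_ids:
            continue
        term = model.term(concept.term)
        if isinstance(term, SimpleTerm):
            if any(label_spans(fragment_text, lab) for lab in term.labels):
                hits.add(concept.id)
    return hits


def _eval_truth(expr: BoolExpr, concepts: set[str]) -> bool:
    if isinstance(expr, ConceptRef):
        return expr.concept in concepts
    if isinstance(expr, Not):
        return not _eval_truth(expr.operand, concepts)
    if isinstance(expr, And):
        return all(_eval_truth(op, concepts) for op in expr.operands)
    if isinstance(expr, Or):
        return any(_eval_truth(op, concepts) for op in expr.operands)
    raise TypeError(expr)


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _filler_run(rng: np.random.Generator, vocab: list[str], k: int) -> list[str]:
    return [_pick(rng, vocab) for _ in range(k)]


def render_document(structure: StructureNode, section_texts: dict[str, str],
                    prefix_map: dict[str, str]) -> bytes:
    """Serialize one document: the structure tree's elements with the given
    per-node-id text content (missing ids become empty elements)."""
    ns_to_prefix = {v: k for k, v in prefix_map.items()}

    def build(node: StructureNode, parent: Optional[etree._Element]) -> etree._Element:
        tag = f"{{{node.namespace}}}{node.local_name}" if node.namespace else node.local_name
        if parent is None:
            nsmap = {ns_to_prefix.get(ns, None): ns for ns in
                     {n.namespace for n in structure.walk() if n.namespace}}
            elem = etree.Element(tag, nsmap=dict(sorted(nsmap.items(),
                                                        key=lambda kv: kv[0] or "")))
        else:
            elem = etree.SubElement(parent, tag)
        if node.id in section_texts:
            elem.text = section_texts[node.id]
        for child in node.children:
            build(child, elem)
        return elem

    root = build(structure, None)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def generate_corpus(spec: CorpusSpec, out_dir: Union[str, os.PathLike]) \
        -> tuple[CorpusHandle, GroundTruthManifest]:
    """Write ``spec.n_docs`` XML documents plus ``manifest.json`` and a spec
    echo, returning the corpus handle and the in-memory manifest."""
    model = spec.model or bundled_model()
    plans = spec.term_plans if spec.term_plans is not None else default_term_plans()
    structure = model.structure
    node_ids = {n.id for n in structure.walk()}
    for plan in plans:
        if plan.section not in node_ids:
            raise ModelError(f"term plan {plan.concept_id!r}: unknown section {plan.section!r}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    vocab = _screen_filler(filler_vocabulary(), model)
    prefix_map = build_prefix_map(model)

    # Plantable sections: leaves (except 'value' leaves, which take their
    # parent's text) and parents of a 'value' leaf.
    text_target: dict[str, str] = {}  # section id -> node id that holds the text
    value_leaves: set[str] = set()
    for node in structure.walk():
        value_children = [c for c in node.children if c.local_name == "value"]
        if value_children:
            text_target[node.id] = value_children[0].id
            value_leaves.update(c.id for c in value_children)
    for node in structure.walk():
        if not node.children and node.id not in value_leaves:
            text_target[node.id] = node.id

    docs: dict[str, DocTruth] = {}
    concept_docs: dict[str, set[str]] = {c: set() for c in model.concepts}

    for i in range(spec.n_docs):
        doc_id = f"doc{i:05d}"
        enumerated = bool(rng.random() < spec.enumeration_prob)
        want_cave = bool(rng.random() < spec.negation_prob)
        want_stray = bool(rng.random() < spec.stray_unit_prob)
        mis_draw = bool(rng.random() < spec.misalignment_prob)

        fragments: dict[str, list[_Fragment]] = {s: [] for s in text_target}
        for plan in plans:
            if rng.random() >= plan.prevalence:
                continue
            surface = _pick(rng, plan.surface_forms)
            tokens = surface.split(" ")
            value = None
            if plan.quantity is not None:
                value, qtokens = realize_quantity(plan.quantity, rng)
                j = int(rng.integers(0, plan.quantity.attach_within + 1))
                tokens = tokens + _filler_run(rng, vocab, j) + qtokens
            fragments[plan.section].append(_Fragment(
                tokens=tokens, plan_concept=plan.concept_id,
                surface=surface, value=value))
        if want_cave:
            fragments["Overall_interpretation"].append(_Fragment(
                tokens=EXCLUSION_PHRASE.split(" "), plan_concept=None,
                surface=EXCLUSION_PHRASE, value=None))
        if want_stray:
            unit = _pick(rng, ["g", "cm"])
            section = _pick(rng, ["Macroscopy", "Overall_interpretation"])
            value, qtokens = realize_quantity(
                QuantityPlan(("uniform", 0.5, 40.0), unit, 0), rng)
            fragments[section].append(_Fragment(
                tokens=qtokens, plan_concept=None, surface=unit,
                value=value, stray=True))

        enum_sections = set(ENUMERABLE_SECTIONS) & set(fragments) if enumerated else set()
        enum_fragments = [f for s in sorted(enum_sections) for f in fragments[s]]
        misaligned = bool(mis_draw and enumerated and len(enum_fragments) >= 2)

        # item counts and ordinal assignment; misaligned documents give every
        # enum-section fragment a pairwise-distinct ordinal, aligned documents
        # put them all in one shared ordinal
        lo, hi = spec.items_range
        n_items: dict[str, int] = {}
        for s in sorted(enum_sections):
            need = len(enum_fragments) if misaligned else 1
            n_items[s] = max(int(rng.integers(lo, hi + 1)), need)
        if enum_sections and enum_fragments:
            if misaligned:
                perm = rng.permutation(min(n_items.values())) + 1
                for frag, o in zip(enum_fragments, perm):
                    frag.ordinal = int(o)
            else:
                shared = int(rng.integers(1, min(n_items.values()) + 1))
                for frag in enum_fragments:
                    frag.ordinal = shared

        # assemble per-section text; fragments occupy indivisible cells so a
        # later insertion can never split an earlier fragment
        texts: dict[str, str] = {}
        for section in sorted(text_target):
            frags = fragments.get(section, [])
            if section in enum_sections:
                items: list[list[list[str]]] = []
                for item_no in range(1, n_items[section] + 1):
                    cells = [[f"{item_no}."]] + \
                        [[w] for w in _filler_run(rng, vocab, int(rng.integers(3, 8)))]
                    items.append(cells)
                for frag in frags:
                    cells = items[(frag.ordinal or 1) - 1]
                    slot = int(rng.integers(1, len(cells) + 1))
                    cells.insert(slot, frag.tokens)
                texts[text_target[section]] = "\n".join(
                    " ".join(tok for cell in cells for tok in cell) for cells in items)
            else:
                cells = [[w] for w in _filler_run(rng, vocab, int(rng.integers(4, 10)))]
                for frag in frags:
                    slot = int(rng.integers(0, len(cells) + 1))
                    cells.insert(slot, frag.tokens)
                texts[text_target[section]] = " ".join(
                    tok for cell in cells for tok in cell)

        # construction-time registration: concepts matched by planted fragments
        matched: set[str] = set()
        plantings: list[PlantingRecord] = []
        for section, frags in fragments.items():
            for frag in frags:
                frag_text = " ".join(frag.tokens)
                hits = _fragment_concept_matches(
                    frag_text, (section, text_target[section]), model)
                matched |= hits
                nominal = frag.plan_concept
                recorded = sorted(hits | ({nominal} if nominal else set()))
                if not recorded and frag.stray:
                    recorded = [""]
                for cid in recorded:
                    plantings.append(PlantingRecord(
                        concept_id=cid, section=section, ordinal=frag.ordinal,
                        surface=frag.surface, value=frag.value, stray=frag.stray))
        # composite-term concepts: decided on the final section text
        for concept in model.concepts.values():
            term = model.term(concept.term)
            if isinstance(term, CompositeTerm):
                target = text_target.get(concept.node)
                if target and _composite_spans(normalize(texts.get(target, "")), term, model):
                    matched.add(concept.id)

        for cid in matched:
            concept_docs[cid].add(doc_id)
        docs[doc_id] = DocTruth(doc_id=doc_id, enumerated=enumerated,
                                misaligned=misaligned,
                                plantings=plantings, concepts=sorted(matched))

        payload = render_document(structure, texts, prefix_map)
        (out / f"{doc_id}.xml").write_bytes(payload)

    queries = {
        qid: sorted(d for d, t in docs.items() if _eval_truth(q.expr, set(t.concepts)))
        for qid, q in model.queries.items()
    }
    manifest = GroundTruthManifest(
        docs=docs, queries=queries,
        concepts={c: sorted(s) for c, s in concept_docs.items()})
    manifest.save(out / "manifest.json")

    echo = {
        "n_docs": spec.n_docs, "seed": spec.seed,
        "enumeration_prob": spec.enumeration_prob,
        "misalignment_prob": spec.misalignment_prob,
        "stray_unit_prob": spec.stray_unit_prob,
        "negation_prob": spec.negation_prob,
        "items_range": list(spec.items_range),
        "model": model_to_dict(model),
        # json round-trip turns dataclass tuples into plain lists for YAML
        "term_plans": json.loads(json.dumps([asdict(p) for p in plans])),
    }
    with open(out / "spec_echo.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(echo, fh, allow_unicode=True, sort_keys=True)

    handle = open_corpus(out, prefix_map=prefix_map)
    return handle, manifest
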