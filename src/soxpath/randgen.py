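"""Randomized (model, corpus) pair generation for differential testing.

Draws small random query models — structure trees with mixed namespaces and
duplicated local names, terms with stem / alternation / case-folded labels,
composites with varying word distances, boolean queries with negation — and
matching random corpora whose vocabulary overlaps the term stems, so that
matches and near-misses both occur. Used to cross-check the XPath compiler
against the brute-force matcher on many independent inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from lxml import etree

from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, Not, Or, SearchConcept,
    SearchModel, SearchQuery, SimpleTerm, StructureNode, TermLabel,
)

_STEMS = ["alpha", "beta", "gamma", "delta", "epsil", "zeta", "kappa",
          "lambda", "sigma", "tau", "Befund", "Tumor"]
_SUFFIXES = ["", "", "e", "es", "en", "oid"]
_NAMESPACES = ["urn:rand:a", "urn:rand:b", ""]
_SECTION_NAMES = ["sec_one", "sec_two", "sec_three", "value", "value2", "notes"]


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def random_model(rng: np.random.Generator, max_concepts: int = 10) -> SearchModel:
    root = StructureNode(id="doc", local_name="doc", namespace=_pick(rng, _NAMESPACES))
    n_sections = int(rng.integers(2, 5))
    used: set[tuple[str, str]] = set()
    for i in range(n_sections):
        name = _pick(rng, _SECTION_NAMES)
        ns = _pick(rng, _NAMESPACES)
        if (ns, name) in used:
            continue
        used.add((ns, name))
        sec = StructureNode(id=f"s{i}_{name}", local_name=name, namespace=ns, parent=root)
        root.children.append(sec)
        if rng.random() < 0.3:  # nested leaf, possibly duplicating a name
            leaf = StructureNode(id=f"s{i}_leaf", local_name="value",
                                 namespace=_pick(rng, _NAMESPACES), parent=sec)
            sec.children.append(leaf)
    model = SearchModel(structure=root)

    n_terms = int(rng.integers(2, 6))
    for i in range(n_terms):
        labels = []
        for _ in range(int(rng.integers(1, 3))):
            stem = _pick(rng, _STEMS)
            style = rng.random()
            if style < 0.4:
                pattern = stem + r"(\w)*"
            elif style < 0.6:
                pattern = f"{stem}|{_pick(rng, _STEMS)}"
            else:
                pattern = stem
            labels.append(TermLabel(pattern=pattern,
                                    case_sensitive=bool(rng.random() < 0.8),
                                    whole_word=bool(rng.random() < 0.85)))
        model.simple_terms[f"t{i}"] = SimpleTerm(id=f"t{i}",
                                                 labels=tuple(dict.fromkeys(labels)))

    simple_ids = list(model.simple_terms)
    for i in range(int(rng.integers(0, 3))):
        if len(simple_ids) < 2:
            break
        parts = (_pick(rng, simple_ids), _pick(rng, simple_ids))
        model.composite_terms[f"c{i}"] = CompositeTerm(
            id=f"c{i}", parts=parts, max_distance=int(rng.integers(0, 4)),
            ordered=bool(rng.random() < 0.3))

    term_ids = simple_ids + list(model.composite_terms)
    nodes = [n.id for n in root.walk() if n is not root]
    n_concepts = int(rng.integers(1, max_concepts + 1))
    for i in range(n_concepts):
        model.concepts[f"k{i}"] = SearchConcept(
            id=f"k{i}", term=_pick(rng, term_ids), node=_pick(rng, nodes))

    concept_ids = list(model.concepts)

    def rand_expr(depth: int) -> BoolExpr:
        if depth <= 0 or rng.random() < 0.4:
            return ConceptRef(_pick(rng, concept_ids))
        kind = rng.random()
        if kind < 0.2:
            return Not(rand_expr(depth - 1))
        ops = tuple(rand_expr(depth - 1) for _ in range(int(rng.integers(2, 4))))
        return And(ops) if kind < 0.6 else Or(ops)

    for i in range(int(rng.integers(1, 4))):
        model.queries[f"q{i}"] = SearchQuery(id=f"q{i}", expr=rand_expr(3))
    return model


def random_corpus(rng: np.random.Generator, model: SearchModel, out_dir,
                  n_docs: int = 30) -> list[str]:
    """Write random documents against the model's structure; each section is
    present with probability 0.85 and filled with stem-derived tokens."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = [s + _pick(rng, _SUFFIXES) for s in _STEMS for _ in range(2)]
    vocab += ["und", "mit", "ohne", "x1", "2,5", "(siehe)", "Xalpha", "betaX"]

    def rand_text() -> str:
        k = int(rng.integers(0, 10))
        return " ".join(_pick(rng, vocab) for _ in range(k))

    doc_ids = []
    for d in range(n_docs):
        doc_id = f"r{d:04d}"
        doc_ids.append(doc_id)

        def build(node: StructureNode, parent) -> None:
            tag = (f"{{{node.namespace}}}{node.local_name}"
                   if node.namespace else node.local_name)
            elem = (etree.Element(tag) if parent is None
                    else etree.SubElement(parent, tag))
            if not node.children:
                elem.text = rand_text()
            else:
                elem.text = rand_text() if rng.random() < 0.3 else None
                for child in node.children:
                    if rng.random() < 0.85:
                        build(child, elem)
            if parent is None:
                (out / f"{doc_id}.xml").write_bytes(
                    etree.tostring(elem, xml_declaration=True, encoding="UTF-8"))

        build(model.structure, None)
    return doc_ids
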