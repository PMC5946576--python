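"""Read search models from OWL files (RDF/XML or Turtle) via rdflib.

The expected class layout follows the search-ontology vocabulary:
``Simple_Term`` / ``Composite_Term`` individuals carry ``rdfs:label`` regex
patterns and ``has_part`` / ``max_distance``; ``Search_Concept`` classes are
described by ``someValuesFrom`` restrictions on ``described_by`` (the term)
and ``in`` (the structure node); ``Search_Query`` classes hold a boolean
class expression (``intersectionOf`` / ``unionOf`` / ``complementOf``) over
concept classes, plus an optional ``xpath`` annotation. ``XML_Structure``
nodes carry ``local_name`` / ``namespace`` and an ordered ``children`` list.
Upper-level (GFO/search-ontology) typing triples are accepted and ignored.

The vocabulary IRIs are configurable; the defaults use the class names
above under one ``sox`` namespace.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL

from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, ModelError, Not, Or,
    SearchConcept, SearchModel, SearchQuery, SimpleTerm, StructureNode,
    TermLabel,
)

DEFAULT_BASE = "http://example.org/sox#"


@dataclass(frozen=True)
class OwlVocabulary:
    """Configurable IRIs of the ontology vocabulary."""

    base: str = DEFAULT_BASE

    @property
    def ns(self) -> Namespace:
        return Namespace(self.base)

    def __getattr__(self, name: str):  # class/property terms by name
        raise AttributeError(name)

    def term(self, name: str) -> URIRef:
        return self.ns[name]


def local_id(iri: URIRef) -> str:
    text = str(iri)
    for sep in ("#", "/"):
        if sep in text:
            text = text.rsplit(sep, 1)[1]
    return text


def _rdf_format(path: str, explicit: Optional[str]) -> str:
    if explicit:
        return explicit
    ext = os.path.splitext(path)[1].lower()
    return "turtle" if ext == ".ttl" else "xml"


def _opt_literal(graph: Graph, subject, predicate) -> Optional[str]:
    value = graph.value(subject, predicate)
    return str(value) if value is not None else None


def _ordered_objects(graph: Graph, subject, list_pred, repeated_pred) -> list:
    """Objects from an rdf:List under ``list_pred`` (order-preserving) or from
    repeated ``repeated_pred`` triples (sorted by local id)."""
    head = graph.value(subject, list_pred)
    if head is not None:
        return list(Collection(graph, head))
    return sorted(graph.objects(subject, repeated_pred), key=lambda o: local_id(o))


def load_owl(path: Union[str, os.PathLike], vocab: Optional[OwlVocabulary] = None,
             rdf_format: Optional[str] = None) -> SearchModel:
    vocab = vocab or OwlVocabulary()
    sox = vocab.ns
    graph = Graph()
    try:
        graph.parse(str(path), format=_rdf_format(str(path), rdf_format))
    except Exception as exc:
        raise ModelError(f"cannot parse OWL file {path}: {exc}") from exc

    # --- structure tree ---------------------------------------------------
    node_iris = sorted(set(graph.subjects(RDF.type, sox["XML_Structure"])),
                       key=local_id)
    if not node_iris:
        raise ModelError("OWL model declares no XML_Structure nodes")
    nodes: dict[URIRef, StructureNode] = {}
    for iri in node_iris:
        nodes[iri] = StructureNode(
            id=local_id(iri),
            local_name=_opt_literal(graph, iri, sox["local_name"]) or local_id(iri),
            namespace=_opt_literal(graph, iri, sox["namespace"]) or "",
        )
    children_of: dict[URIRef, list[URIRef]] = {}
    has_parent: set[URIRef] = set()
    for iri in node_iris:
        kids = _ordered_objects(graph, iri, sox["children"], sox["child"])
        children_of[iri] = kids
        has_parent.update(kids)
    roots = [iri for iri in node_iris if iri not in has_parent]
    if len(roots) != 1:
        raise ModelError(f"structure must have exactly one root, found {len(roots)}")
    for iri in node_iris:
        for kid in children_of[iri]:
            if kid not in nodes:
                raise ModelError(f"structure child {local_id(kid)!r} is not an XML_Structure node")
            nodes[kid].parent = nodes[iri]
            nodes[iri].children.append(nodes[kid])
    model = SearchModel(structure=nodes[roots[0]])

    # --- terms ------------------------------------------------------------
    def term_flags(subject) -> tuple[bool, bool]:
        cs = graph.value(subject, sox["case_sensitive"])
        ww = graph.value(subject, sox["whole_word"])
        return (bool(cs.toPython()) if cs is not None else True,
                bool(ww.toPython()) if ww is not None else True)

    for iri in sorted(set(graph.subjects(RDF.type, sox["Simple_Term"])), key=local_id):
        labels = sorted(str(o) for o in graph.objects(iri, RDFS.label))
        if not labels:
            raise ModelError(f"simple term {local_id(iri)!r} has no labels")
        cs, ww = term_flags(iri)
        model.simple_terms[local_id(iri)] = SimpleTerm(
            id=local_id(iri),
            labels=tuple(dict.fromkeys(
                TermLabel(p, case_sensitive=cs, whole_word=ww) for p in labels)))

    for iri in sorted(set(graph.subjects(RDF.type, sox["Composite_Term"])), key=local_id):
        parts = _ordered_objects(graph, iri, sox["part_list"], sox["has_part"])
        dist = graph.value(iri, sox["max_distance"])
        if dist is None:
            raise ModelError(f"composite term {local_id(iri)!r} lacks max_distance")
        ordered = graph.value(iri, sox["ordered"])
        model.composite_terms[local_id(iri)] = CompositeTerm(
            id=local_id(iri),
            parts=tuple(local_id(p) for p in parts),
            max_distance=int(dist.toPython()),
            ordered=bool(ordered.toPython()) if ordered is not None else False)

    # --- concepts: someValuesFrom restrictions -----------------------------
    def restriction_targets(concept_iri) -> dict[URIRef, URIRef]:
        targets: dict[URIRef, URIRef] = {}
        for sup in graph.objects(concept_iri, RDFS.subClassOf):
            on_prop = graph.value(sup, OWL.onProperty)
            filler = graph.value(sup, OWL.someValuesFrom)
            if on_prop is not None and filler is not None:
                targets[on_prop] = filler
        return targets

    for iri in sorted(set(graph.subjects(RDF.type, sox["Search_Concept"])), key=local_id):
        targets = restriction_targets(iri)
        term = targets.get(sox["described_by"]) or graph.value(iri, sox["described_by"])
        node = targets.get(sox["in"]) or graph.value(iri, sox["in"])
        if term is None or node is None:
            raise ModelError(
                f"concept {local_id(iri)!r} needs described_by and in "
                "(someValuesFrom restrictions or direct assertions)")
        model.concepts[local_id(iri)] = SearchConcept(
            id=local_id(iri), term=local_id(term), node=local_id(node))

    # --- queries: boolean class expressions --------------------------------
    concept_iris = {sox[c] for c in model.concepts}

    def parse_expr(node) -> BoolExpr:
        if isinstance(node, URIRef):
            if node not in concept_iris:
                raise ModelError(f"query references unknown concept {local_id(node)!r}")
            return ConceptRef(local_id(node))
        if isinstance(node, BNode):
            head = graph.value(node, OWL.intersectionOf)
            if head is not None:
                ops = tuple(parse_expr(m) for m in Collection(graph, head))
                return And(ops)
            head = graph.value(node, OWL.unionOf)
            if head is not None:
                ops = tuple(parse_expr(m) for m in Collection(graph, head))
                return Or(ops)
            comp = graph.value(node, OWL.complementOf)
            if comp is not None:
                return Not(parse_expr(comp))
        raise ModelError(f"unsupported class expression node {node!r}")

    for iri in sorted(set(graph.subjects(RDF.type, sox["Search_Query"])), key=local_id):
        exprs = [sup for sup in graph.objects(iri, RDFS.subClassOf)
                 if isinstance(sup, BNode) and graph.value(sup, OWL.onProperty) is None]
        exprs += [eq for eq in graph.objects(iri, OWL.equivalentClass)]
        candidates = [e for e in exprs if isinstance(e, (BNode, URIRef))]
        if not candidates:
            raise ModelError(f"query {local_id(iri)!r} has no boolean class expression")
        expr = parse_expr(candidates[0])
        model.queries[local_id(iri)] = SearchQuery(
            id=local_id(iri), expr=expr,
            xpath_annotation=_opt_literal(graph, iri, sox["xpath"]))

    return model


def annotate_owl(source: Union[str, os.PathLike], compiled, out: Union[str, os.PathLike],
                 vocab: Optional[OwlVocabulary] = None,
                 rdf_format: Optional[str] = None) -> None:
    """Copy an OWL model with each compiled query's XPath written as an
    ``xpath`` annotation on the query class (existing annotations replaced)."""
    vocab = vocab or OwlVocabulary()
    sox = vocab.ns
    fmt = _rdf_format(str(source), rdf_format)
    graph = Graph()
    graph.parse(str(source), format=fmt)
    queries = {local_id(s): s for s in graph.subjects(RDF.type, sox["Search_Query"])}
    for cq in compiled:
        if cq.query_id not in queries:
            raise ModelError(f"unknown query id {cq.query_id!r} in OWL source")
        subject = queries[cq.query_id]
        graph.remove((subject, sox["xpath"], None))
        graph.add((subject, sox["xpath"], Literal(cq.xpath)))
    graph.serialize(destination=str(out), format=fmt)
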