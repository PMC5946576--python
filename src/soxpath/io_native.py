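"""Native YAML serialization of search models.

The native format is a plain YAML document with top-level keys ``structure``
(nested name/namespace/children), ``simple_terms``, ``composite_terms``,
``concepts`` and ``queries``; query expressions use a small prefix
s-expression syntax over concept ids, e.g. ``[and, [not, blister], g_unit]``.
Loading then saving then loading again is a fixed point.
"""

from __future__ import annotations

import os
from typing import Any, Union

import yaml

from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, ModelError, Not, Or,
    SearchConcept, SearchModel, SearchQuery, SimpleTerm, StructureNode,
    TermLabel, build_structure, validate_model,
)


def parse_expr(raw: Any) -> BoolExpr:
    """Parse a prefix s-expression (nested YAML lists) into a BoolExpr."""
    if isinstance(raw, str):
        return ConceptRef(raw)
    if not isinstance(raw, list) or not raw:
        raise ModelError(f"malformed query expression: {raw!r}")
    head = raw[0]
    if head == "not":
        if len(raw) != 2:
            raise ModelError(f"'not' takes exactly one operand: {raw!r}")
        return Not(parse_expr(raw[1]))
    if head in ("and", "or"):
        operands = tuple(parse_expr(x) for x in raw[1:])
        if len(operands) < 2:
            raise ModelError(f"{head!r} needs >= 2 operands: {raw!r}")
        return And(operands) if head == "and" else Or(operands)
    raise ModelError(f"unknown operator {head!r} in query expression")


def unparse_expr(expr: BoolExpr) -> Any:
    if isinstance(expr, ConceptRef):
        return expr.concept
    if isinstance(expr, Not):
        return ["not", unparse_expr(expr.operand)]
    op = "and" if isinstance(expr, And) else "or"
    return [op] + [unparse_expr(x) for x in expr.operands]


def _parse_label(raw: Union[str, dict]) -> TermLabel:
    if isinstance(raw, str):
        return TermLabel(pattern=raw)
    if not isinstance(raw, dict) or "pattern" not in raw:
        raise ModelError(f"malformed label: {raw!r}")
    return TermLabel(
        pattern=raw["pattern"],
        case_sensitive=bool(raw.get("case_sensitive", True)),
        whole_word=bool(raw.get("whole_word", True)),
    )


def model_from_dict(doc: dict) -> SearchModel:
    if not isinstance(doc, dict) or "structure" not in doc:
        raise ModelError("native model needs a top-level 'structure' mapping")
    model = SearchModel(structure=build_structure(doc["structure"]))

    for term_id, labels in (doc.get("simple_terms") or {}).items():
        if not labels:
            raise ModelError(f"simple term {term_id!r} has no labels")
        parsed = tuple(_parse_label(l) for l in labels)
        # dedupe by (pattern, flags), preserving order
        unique = tuple(dict.fromkeys(parsed))
        model.simple_terms[term_id] = SimpleTerm(id=term_id, labels=unique)

    for term_id, spec in (doc.get("composite_terms") or {}).items():
        if not isinstance(spec, dict) or "max_distance" not in spec:
            raise ModelError(f"composite term {term_id!r} lacks max_distance")
        model.composite_terms[term_id] = CompositeTerm(
            id=term_id,
            parts=tuple(spec.get("parts") or ()),
            max_distance=int(spec["max_distance"]),
            ordered=bool(spec.get("ordered", False)),
        )

    for cid, spec in (doc.get("concepts") or {}).items():
        if not isinstance(spec, dict) or "term" not in spec or "node" not in spec:
            raise ModelError(f"concept {cid!r} needs 'term' and 'node'")
        model.concepts[cid] = SearchConcept(id=cid, term=spec["term"], node=spec["node"])

    for qid, spec in (doc.get("queries") or {}).items():
        if isinstance(spec, dict) and "expr" in spec:
            query = SearchQuery(id=qid, expr=parse_expr(spec["expr"]),
                                xpath_annotation=spec.get("xpath"))
        else:
            query = SearchQuery(id=qid, expr=parse_expr(spec))
        model.queries[qid] = query

    _check_references(model)
    return model


def _check_references(model: SearchModel) -> None:
    """Fail fast on dangling references, naming the missing id."""
    node_ids = {n.id for n in model.structure.walk()}
    for comp in model.composite_terms.values():
        for part in comp.parts:
            if part not in model.simple_terms:
                raise ModelError(
                    f"composite term {comp.id!r} references unknown simple term {part!r}")
    for concept in model.concepts.values():
        if concept.term not in model.simple_terms and concept.term not in model.composite_terms:
            raise ModelError(f"concept {concept.id!r} references unknown term {concept.term!r}")
        if concept.node not in node_ids:
            raise ModelError(f"concept {concept.id!r} references unknown node {concept.node!r}")
    for query in model.queries.values():
        for cid in model.concept_ids_in(query.expr):
            if cid not in model.concepts:
                raise ModelError(f"query {query.id!r} references unknown concept {cid!r}")


def _structure_to_dict(node: StructureNode) -> dict:
    out: dict[str, Any] = {"name": node.local_name}
    if node.namespace:
        out["namespace"] = node.namespace
    if node.id != node.local_name:
        out["id"] = node.id
    if node.children:
        out["children"] = [_structure_to_dict(c) for c in node.children]
    return out


def _label_to_obj(label: TermLabel) -> Union[str, dict]:
    if label.case_sensitive and label.whole_word:
        return label.pattern
    out: dict[str, Any] = {"pattern": label.pattern}
    if not label.case_sensitive:
        out["case_sensitive"] = False
    if not label.whole_word:
        out["whole_word"] = False
    return out


def model_to_dict(model: SearchModel) -> dict:
    doc: dict[str, Any] = {"structure": _structure_to_dict(model.structure)}
    if model.simple_terms:
        doc["simple_terms"] = {
            t.id: [_label_to_obj(l) for l in t.labels] for t in model.simple_terms.values()
        }
    if model.composite_terms:
        doc["composite_terms"] = {
            c.id: {"parts": list(c.parts), "max_distance": c.max_distance,
                   **({"ordered": True} if c.ordered else {})}
            for c in model.composite_terms.values()
        }
    if model.concepts:
        doc["concepts"] = {
            c.id: {"term": c.term, "node": c.node} for c in model.concepts.values()
        }
    if model.queries:
        queries: dict[str, Any] = {}
        for q in model.queries.values():
            if q.xpath_annotation is None:
                queries[q.id] = unparse_expr(q.expr)
            else:
                queries[q.id] = {"expr": unparse_expr(q.expr), "xpath": q.xpath_annotation}
        doc["queries"] = queries
    return doc


def load_native(path: Union[str, os.PathLike]) -> SearchModel:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelError(f"cannot parse {path}: {exc}") from exc
    return model_from_dict(doc)


def loads_native(text: str) -> SearchModel:
    return model_from_dict(yaml.safe_load(text))


def save_native(model: SearchModel, path: Union[str, os.PathLike]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, allow_unicode=True, sort_keys=False,
                       default_flow_style=None)


def load_model(path: Union[str, os.PathLike], format: str = "auto") -> SearchModel:
    """Load a search model from the native YAML or an OWL (RDF/XML, Turtle) file.

    ``format`` is ``native``, ``owl`` or ``auto`` (extension-based: .owl/.rdf/.ttl
    are OWL, everything else native). The returned model is fully resolved but
    not necessarily valid — run :func:`soxpath.model.validate_model` for the
    diagnostic pass.
    """
    fmt = format
    if fmt == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "owl" if ext in (".owl", ".rdf", ".ttl", ".xml") else "native"
    if fmt == "native":
        return load_native(path)
    if fmt == "owl":
        from .io_owl import load_owl
        return load_owl(path)
    raise ModelError(f"unknown model format {format!r}")
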