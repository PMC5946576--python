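"""Compile search queries into XPath expressions.

Each search query — a boolean tree over concepts, each concept a term bound
to one structure node — compiles to a single XPath that selects the document
root of every matching document. A simple term becomes a disjunction of one
regex ``matches()`` test per label over the section's normalized string
value; a composite term becomes a disjunction over the cross product of its
parts' labels (and over both part orders when unordered), joined by a
token-counting proximity gap ``(?:\\s[^\\s]+){0,d}\\s`` where ``d`` is the
composite's ``max_distance``: at most ``d`` whitespace-delimited words may
sit between consecutive part matches, and ``d = 0`` means the next part
immediately follows.

The emitted expressions use XPath 2.0 ``matches()`` call syntax; the bundled
engine evaluates them with a registered ``matches`` extension backed by
Python's regex engine, so label patterns are restricted to the regex subset
shared by both dialects (see :func:`check_pattern`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, ModelError, Not, Or,
    SearchConcept, SearchModel, SearchQuery, SimpleTerm, StructureNode,
    TermLabel, WORD_CLASS, resolve_path,
)


class PatternError(ModelError):
    """A label pattern outside the supported regex subset (or non-compiling)."""


# Constructs whose semantics differ between Python re and XPath fn:matches,
# or that only one dialect supports. Label patterns must avoid all of them.
_FORBIDDEN = [
    (re.compile(r"\(\?[=!<]"), "lookaround assertions"),
    (re.compile(r"\(\?P"), "named groups"),
    (re.compile(r"(?<!\\)\\[1-9]"), "backreferences"),
    (re.compile(r"\(\?[aiLmsux]+\)"), "global inline flags"),
    (re.compile(r"\\[bBAZ]"), "anchor escapes"),
]


def check_pattern(pattern: str) -> None:
    """Reject empty, non-compiling, or dialect-divergent label patterns."""
    if not pattern:
        raise PatternError("empty label pattern")
    for rx, what in _FORBIDDEN:
        if rx.search(pattern):
            raise PatternError(f"pattern {pattern!r} uses {what}, outside the portable subset")
    try:
        re.compile(pattern)
    except re.error as exc:
        raise PatternError(f"pattern {pattern!r} does not compile: {exc}") from exc


_LB = f"(?<!{WORD_CLASS})"   # word boundary on the left (fixed-width lookbehind)
_RB = f"(?!{WORD_CLASS})"    # word boundary on the right


def _core(label: TermLabel) -> str:
    """Label pattern grouped, with case folding via a scoped inline flag."""
    check_pattern(label.pattern)
    return f"(?{'' if label.case_sensitive else 'i'}:{label.pattern})" \
        if not label.case_sensitive else f"(?:{label.pattern})"


def compile_label(label: TermLabel) -> str:
    """Full-match regex for one label: grouped pattern plus word boundaries."""
    core = _core(label)
    if label.whole_word:
        return f"{_LB}{core}{_RB}"
    return core


def gap(max_distance: int) -> str:
    """Proximity gap between consecutive composite parts: at most
    ``max_distance`` intervening whitespace-delimited tokens."""
    return rf"(?:\s[^\s]+){{0,{max_distance}}}\s"


def composite_alternatives(term: CompositeTerm, model: SearchModel) -> list[str]:
    """All proximity regexes of a composite term.

    One alternative per tuple of the cross product of the parts' label lists;
    with ``ordered`` false, the forward part order is enumerated first, then
    the reversed order. Tuple order is lexicographic over label indices, so
    output is deterministic.
    """
    parts = [model.simple_terms[p] for p in term.parts]
    orders = [parts] if term.ordered else [parts, list(reversed(parts))]
    if not term.ordered and len(parts) == 2 and parts[0] is parts[1]:
        orders = [parts]  # both orders identical
    out: list[str] = []
    g = gap(term.max_distance)
    for order in orders:
        tuples: list[list[TermLabel]] = [[]]
        for part in order:
            tuples = [t + [lab] for t in tuples for lab in part.labels]
        for labels in tuples:
            first, last = labels[0], labels[-1]
            body = g.join(_core(lab) for lab in labels)
            lb = _LB if first.whole_word else ""
            rb = _RB if last.whole_word else ""
            out.append(f"{lb}{body}{rb}")
    return out


def term_regexes(term: SimpleTerm | CompositeTerm, model: SearchModel) -> list[tuple[str, str]]:
    """``(description, regex)`` pairs for a term — one per label for a simple
    term, one per cross-product alternative for a composite."""
    if isinstance(term, SimpleTerm):
        return [(lab.pattern, compile_label(lab)) for lab in term.labels]
    return [(f"{term.id}[{i}]", rx) for i, rx in enumerate(composite_alternatives(term, model))]


# --- XPath emission -------------------------------------------------------

@dataclass(frozen=True)
class CompiledPredicate:
    xpath_fragment: str
    concept_id: str
    polarity: str = "positive"  # or "negated"


@dataclass(frozen=True)
class CompiledQuery:
    query_id: str
    xpath: str
    prefix_map: dict[str, str] = field(hash=False)


def build_prefix_map(model: SearchModel) -> dict[str, str]:
    """Assign ``ns1``, ``ns2``, … to the distinct namespaces of the structure
    tree, in preorder of first appearance. The empty namespace gets no prefix."""
    prefixes: dict[str, str] = {}
    seen: dict[str, str] = {}
    for node in model.structure.walk():
        ns = node.namespace
        if ns and ns not in seen:
            prefix = f"ns{len(seen) + 1}"
            seen[ns] = prefix
            prefixes[prefix] = ns
    return prefixes


def _step(qname: tuple[str, str], ns_to_prefix: dict[str, str]) -> str:
    ns, name = qname
    return f"{ns_to_prefix[ns]}:{name}" if ns else name


def xpath_literal(s: str) -> str:
    """Quote a string as an XPath literal (concat() when both quotes occur)."""
    if "'" not in s:
        return f"'{s}'"
    if '"' not in s:
        return f'"{s}"'
    parts = [f'"{p}"' for p in s.split("'")]
    return "concat(" + ", '\\'', ".join(parts) + ")"


_TEXT = "normalize-space(string(.))"


def _predicate_body(regexes: list[str]) -> str:
    tests = [f"matches({_TEXT}, {xpath_literal(rx)})" for rx in regexes]
    return " or ".join(tests)


def _relative_path(model: SearchModel, node: StructureNode,
                   ns_to_prefix: dict[str, str]) -> str:
    steps = resolve_path(model, node)[1:]  # drop the root step
    return "/".join(_step(q, ns_to_prefix) for q in steps)


def compile_simple_term(term: SimpleTerm, node: StructureNode, model: SearchModel,
                        concept_id: str = "") -> CompiledPredicate:
    """Existential test: at least one element at the node's location path has
    a string value matching at least one label (one disjunct per label)."""
    ns_to_prefix = {v: k for k, v in build_prefix_map(model).items()}
    body = _predicate_body([compile_label(lab) for lab in term.labels])
    rel = _relative_path(model, node, ns_to_prefix)
    frag = f"{rel}[{body}]" if rel else f"self::*[{body}]"
    return CompiledPredicate(frag, concept_id or term.id, "positive")


def compile_composite_term(term: CompositeTerm, node: StructureNode, model: SearchModel,
                           concept_id: str = "") -> CompiledPredicate:
    ns_to_prefix = {v: k for k, v in build_prefix_map(model).items()}
    body = _predicate_body(composite_alternatives(term, model))
    rel = _relative_path(model, node, ns_to_prefix)
    frag = f"{rel}[{body}]" if rel else f"self::*[{body}]"
    return CompiledPredicate(frag, concept_id or term.id, "positive")


def compile_concept(concept: SearchConcept, model: SearchModel) -> CompiledPredicate:
    term = model.term(concept.term)
    node = model.node_by_id(concept.node)
    if isinstance(term, SimpleTerm):
        return compile_simple_term(term, node, model, concept.id)
    return compile_composite_term(term, node, model, concept.id)


def compile_expr(expr: BoolExpr, model: SearchModel) -> str:
    if isinstance(expr, ConceptRef):
        if expr.concept not in model.concepts:
            raise ModelError(f"unresolved concept reference {expr.concept!r}")
        return compile_concept(model.concepts[expr.concept], model).xpath_fragment
    if isinstance(expr, Not):
        return f"not({compile_expr(expr.operand, model)})"
    joiner = " and " if isinstance(expr, And) else " or "
    return "(" + joiner.join(compile_expr(op, model) for op in expr.operands) + ")"


def compile_query(query: SearchQuery, model: SearchModel) -> CompiledQuery:
    """Compile one query to an XPath selecting matching document roots.

    Pure function of ``(query, model)``: label order, tuple order and prefix
    assignment are all deterministic.
    """
    prefix_map = build_prefix_map(model)
    ns_to_prefix = {v: k for k, v in prefix_map.items()}
    root_step = _step(model.structure.qname(), ns_to_prefix)
    body = compile_expr(query.expr, model)
    xpath = f"/{root_step}[{body}]"
    used = {p for p in prefix_map if re.search(rf"(?<![\w]){p}:", xpath)}
    return CompiledQuery(query.id, xpath, {p: prefix_map[p] for p in sorted(used)})


def compile_model(model: SearchModel) -> dict[str, CompiledQuery]:
    """Compile every query of the model, keyed by query id."""
    return {qid: compile_query(q, model) for qid, q in model.queries.items()}


def annotate_model(model: SearchModel, compiled: list[CompiledQuery], out) -> None:
    """Write the model in the native format with each compiled query's XPath
    stored as its annotation. Re-annotation overwrites; unknown ids raise."""
    from .io_native import save_native
    by_id = {c.query_id: c for c in compiled}
    unknown = set(by_id) - set(model.queries)
    if unknown:
        raise ModelError(f"unknown query id(s) in annotation: {sorted(unknown)}")
    for qid, cq in by_id.items():
        model.queries[qid].xpath_annotation = cq.xpath
    save_native(model, out)
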