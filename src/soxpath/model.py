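"""Domain model for ontology-defined search queries over section-structured XML.

The model mirrors the search-ontology view of a query: a hierarchical
*structure tree* describing the XML document layout (namespace-qualified
element names), *search terms* (simple terms carrying regex labels, composite
terms combining simple terms under a word-distance bound), *search concepts*
binding a term to one structure node, and *search queries* — boolean
expression trees over concepts, the unit later compiled to a single XPath.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*$")

#: Characters counted as word constituents for whole-word boundaries.
#: Python's unicode \w already covers the German umlauts; they are spelled
#: out so the class reads as the contract it is.
WORD_CLASS = r"[\wäöüÄÖÜß]"


class ModelError(ValueError):
    """Raised on unrecoverable model defects (parse/reference failures)."""


@dataclass(eq=False)
class StructureNode:
    """One element in the XML structure tree.

    ``id`` defaults to ``local_name`` when unambiguous; ``namespace`` may be
    empty for unqualified elements.
    """

    id: str
    local_name: str
    namespace: str = ""
    parent: Optional["StructureNode"] = field(default=None, repr=False)
    children: list["StructureNode"] = field(default_factory=list)

    def qname(self) -> tuple[str, str]:
        return (self.namespace, self.local_name)

    def walk(self) -> Iterator["StructureNode"]:
        """Preorder traversal of the subtree rooted here."""
        yield self
        for child in self.children:
            yield from child.walk()

    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    # Structural equality: compare content and children, never the parent
    # link (it would recurse upward).
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureNode):
            return NotImplemented
        return (
            self.id == other.id
            and self.local_name == other.local_name
            and self.namespace == other.namespace
            and self.children == other.children
        )

    def __hash__(self) -> int:
        return id(self)


@dataclass(frozen=True)
class TermLabel:
    """A regex label of a simple term (a word-stem pattern like ``florid(\\w)*``)."""

    pattern: str
    case_sensitive: bool = True
    whole_word: bool = True


@dataclass(frozen=True)
class SimpleTerm:
    id: str
    labels: tuple[TermLabel, ...]


@dataclass(frozen=True)
class CompositeTerm:
    """An ordered combination of simple terms within a word-distance bound.

    ``max_distance`` counts the whitespace-delimited tokens allowed between
    consecutive part matches; 0 means immediately adjacent words. With
    ``ordered`` false (the default) both part orders are accepted.
    """

    id: str
    parts: tuple[str, ...]  # SimpleTerm ids, length >= 2
    max_distance: int
    ordered: bool = False


@dataclass(frozen=True)
class SearchConcept:
    """A term expected inside one structure node ("X in Y")."""

    id: str
    term: str  # SimpleTerm or CompositeTerm id
    node: str  # StructureNode id


# --- Boolean expression tree over concepts -------------------------------

@dataclass(frozen=True)
class ConceptRef:
    concept: str


@dataclass(frozen=True)
class And:
    operands: tuple["BoolExpr", ...]


@dataclass(frozen=True)
class Or:
    operands: tuple["BoolExpr", ...]


@dataclass(frozen=True)
class Not:
    operand: "BoolExpr"


BoolExpr = Union[ConceptRef, And, Or, Not]


@dataclass
class SearchQuery:
    id: str
    expr: BoolExpr
    xpath_annotation: Optional[str] = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SearchQuery):
            return NotImplemented
        return (
            self.id == other.id
            and self.expr == other.expr
            and self.xpath_annotation == other.xpath_annotation
        )


@dataclass
class SearchModel:
    """A fully-resolved query model: structure tree plus keyed collections."""

    structure: StructureNode
    simple_terms: dict[str, SimpleTerm] = field(default_factory=dict)
    composite_terms: dict[str, CompositeTerm] = field(default_factory=dict)
    concepts: dict[str, SearchConcept] = field(default_factory=dict)
    queries: dict[str, SearchQuery] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------

    def node_by_id(self, node_id: str) -> StructureNode:
        for node in self.structure.walk():
            if node.id == node_id:
                return node
        raise ModelError(f"unknown structure node: {node_id!r}")

    def term(self, term_id: str) -> Union[SimpleTerm, CompositeTerm]:
        if term_id in self.simple_terms:
            return self.simple_terms[term_id]
        if term_id in self.composite_terms:
            return self.composite_terms[term_id]
        raise ModelError(f"unknown term: {term_id!r}")

    def concept_ids_in(self, expr: BoolExpr) -> list[str]:
        """Concept ids referenced by ``expr``, in first-occurrence order."""
        out: list[str] = []

        def visit(e: BoolExpr) -> None:
            if isinstance(e, ConceptRef):
                if e.concept not in out:
                    out.append(e.concept)
            elif isinstance(e, Not):
                visit(e.operand)
            else:
                for op in e.operands:
                    visit(op)

        visit(expr)
        return out

    def positive_concept_ids(self, expr: BoolExpr) -> list[str]:
        """Concepts occurring under an even number of negations."""
        out: list[str] = []

        def visit(e: BoolExpr, neg: bool) -> None:
            if isinstance(e, ConceptRef):
                if not neg and e.concept not in out:
                    out.append(e.concept)
            elif isinstance(e, Not):
                visit(e.operand, not neg)
            else:
                for op in e.operands:
                    visit(op, neg)

        visit(expr, False)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SearchModel):
            return NotImplemented
        return (
            self.structure == other.structure
            and self.simple_terms == other.simple_terms
            and self.composite_terms == other.composite_terms
            and self.concepts == other.concepts
            and self.queries == other.queries
        )


# --- Validation -----------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """A machine-readable validation finding."""

    code: str
    subject: str
    message: str


def _pattern_compiles(pattern: str) -> bool:
    try:
        re.compile(pattern)
        return True
    except re.error:
        return False


def validate_model(model: SearchModel) -> list[Diagnostic]:
    """Check every model invariant; return diagnostics (empty list = valid)."""
    diags: list[Diagnostic] = []

    # structure: tree-ness, sibling uniqueness, id uniqueness
    seen: set[int] = set()
    stack = [model.structure]
    nodes: list[StructureNode] = []
    is_tree = True
    while stack:
        node = stack.pop()
        if id(node) in seen:
            is_tree = False
            diags.append(Diagnostic("structure_not_tree", node.id,
                                    f"node {node.id!r} reachable twice (cycle or DAG)"))
            break
        seen.add(id(node))
        nodes.append(node)
        qnames = [c.qname() for c in node.children]
        if len(qnames) != len(set(qnames)):
            diags.append(Diagnostic("duplicate_sibling", node.id,
                                    f"duplicate (namespace, name) among children of {node.id!r}"))
        for child in node.children:
            if child.parent is not node:
                diags.append(Diagnostic("bad_parent_link", child.id,
                                        f"node {child.id!r} has inconsistent parent link"))
            stack.append(child)

    if is_tree:
        node_ids = [n.id for n in nodes]
        if len(node_ids) != len(set(node_ids)):
            dupes = sorted({i for i in node_ids if node_ids.count(i) > 1})
            diags.append(Diagnostic("duplicate_node_id", dupes[0],
                                    f"structure node ids not unique: {dupes}"))

    all_ids = [n.id for n in nodes] + list(model.simple_terms) + \
        list(model.composite_terms) + list(model.concepts) + list(model.queries)
    if len(all_ids) != len(set(all_ids)):
        dupes = sorted({i for i in all_ids if all_ids.count(i) > 1})
        diags.append(Diagnostic("duplicate_id", dupes[0],
                                f"ids not globally unique: {dupes}"))

    for ident in all_ids:
        if not ID_RE.match(ident):
            diags.append(Diagnostic("bad_id", ident, f"id {ident!r} is not a valid identifier"))

    # simple terms
    for term in model.simple_terms.values():
        if not term.labels:
            diags.append(Diagnostic("term_without_labels", term.id,
                                    f"simple term {term.id!r} has no labels"))
        for label in term.labels:
            if not label.pattern:
                diags.append(Diagnostic("empty_pattern", term.id,
                                        f"term {term.id!r} has an empty label pattern"))
            elif not _pattern_compiles(label.pattern):
                diags.append(Diagnostic("bad_pattern", term.id,
                                        f"term {term.id!r}: pattern {label.pattern!r} does not compile"))
        if len(set(term.labels)) != len(term.labels):
            diags.append(Diagnostic("duplicate_label", term.id,
                                    f"term {term.id!r} repeats a label"))

    # composite terms
    for comp in model.composite_terms.values():
        if len(comp.parts) < 2:
            diags.append(Diagnostic("composite_arity", comp.id,
                                    f"composite term {comp.id!r} needs >= 2 parts"))
        for part in comp.parts:
            if part in model.composite_terms:
                diags.append(Diagnostic("composite_nesting", comp.id,
                                        f"composite term {comp.id!r} nests composite {part!r}"))
            elif part not in model.simple_terms:
                diags.append(Diagnostic("dangling_reference", comp.id,
                                        f"composite term {comp.id!r} references unknown part {part!r}"))
        if comp.max_distance < 0:
            diags.append(Diagnostic("bad_max_distance", comp.id,
                                    f"composite term {comp.id!r}: max_distance must be >= 0"))

    node_id_set = {n.id for n in nodes} if is_tree else set()
    for concept in model.concepts.values():
        if concept.term not in model.simple_terms and concept.term not in model.composite_terms:
            diags.append(Diagnostic("dangling_reference", concept.id,
                                    f"concept {concept.id!r} references unknown term {concept.term!r}"))
        if is_tree and concept.node not in node_id_set:
            diags.append(Diagnostic("dangling_reference", concept.id,
                                    f"concept {concept.id!r} references unknown node {concept.node!r}"))

    for query in model.queries.values():
        def check(e: BoolExpr, qid: str = query.id) -> None:
            if isinstance(e, ConceptRef):
                if e.concept not in model.concepts:
                    diags.append(Diagnostic("dangling_reference", qid,
                                            f"query {qid!r} references unknown concept {e.concept!r}"))
            elif isinstance(e, Not):
                check(e.operand, qid)
            elif isinstance(e, (And, Or)):
                if len(e.operands) < 2:
                    diags.append(Diagnostic("bool_arity", qid,
                                            f"query {qid!r}: and/or needs >= 2 operands"))
                for op in e.operands:
                    check(op, qid)
            else:  # pragma: no cover - type guard
                diags.append(Diagnostic("bad_expr", qid, f"query {qid!r}: unknown node {e!r}"))
        check(query.expr)

    return diags


def resolve_path(model: SearchModel, node: StructureNode) -> list[tuple[str, str]]:
    """Location path from the structure root to ``node``.

    Returns the ordered list of ``(namespace, local_name)`` steps; the first
    step is always the root. Raises :class:`ModelError` for nodes outside the
    model's tree.
    """
    steps: list[tuple[str, str]] = []
    cur: Optional[StructureNode] = node
    while cur is not None:
        steps.append(cur.qname())
        cur = cur.parent
    steps.reverse()
    # membership check: walking up must have ended at the model's root
    top = node
    while top.parent is not None:
        top = top.parent
    if top is not model.structure:
        raise ModelError(f"node {node.id!r} does not belong to the model's structure tree")
    return steps


def build_structure(spec: dict, parent: Optional[StructureNode] = None) -> StructureNode:
    """Build a structure tree from nested ``{name, namespace?, id?, children?}`` dicts."""
    if "name" not in spec:
        raise ModelError("structure node needs a 'name'")
    node = StructureNode(
        id=spec.get("id", spec["name"]),
        local_name=spec["name"],
        namespace=spec.get("namespace", "") or "",
        parent=parent,
    )
    for child_spec in spec.get("children") or []:
        node.children.append(build_structure(child_spec, parent=node))
    return node
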