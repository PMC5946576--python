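"""Independent brute-force query matcher, used to cross-check the compiler.

This walks documents with the structure tree, extracts normalized section
texts, applies label regexes and token-counted proximity directly, and
evaluates the boolean expression in Python. It deliberately shares nothing
with the XPath compiler beyond the model types and the tokenizer: label
matching re-implements whole-word boundaries by inspecting neighbour
characters, and composite proximity is checked by counting the tokens
between part matches rather than by a joined gap regex.
"""

from __future__ import annotations

import os
import re
from typing import Union

from lxml import etree

from .model import (
    And, BoolExpr, CompositeTerm, ConceptRef, Not, Or, SearchConcept,
    SearchModel, SearchQuery, SimpleTerm, StructureNode, TermLabel, WORD_CLASS,
)
from .text import normalize

_WORD_CHAR = re.compile(WORD_CLASS)


def _is_word_char(ch: str) -> bool:
    return bool(_WORD_CHAR.match(ch))


def label_spans(text: str, label: TermLabel) -> list[tuple[int, int]]:
    """All spans where the raw label pattern matches, every start position
    tried, whole-word labels filtered by neighbour-character inspection."""
    flags = 0 if label.case_sensitive else re.IGNORECASE
    rx = re.compile(label.pattern, flags)
    spans = []
    for i in range(len(text) + 1):
        m = rx.match(text, i)
        if not m or m.end() == m.start():
            continue
        if label.whole_word:
            if m.start() > 0 and _is_word_char(text[m.start() - 1]):
                continue
            if m.end() < len(text) and _is_word_char(text[m.end()]):
                continue
        spans.append((m.start(), m.end()))
    return spans


def _gap_ok(text: str, end_first: int, start_second: int, max_distance: int) -> bool:
    """True when the stretch between two part matches is whitespace-bounded
    and holds at most ``max_distance`` whitespace-delimited tokens."""
    if start_second <= end_first:
        return False
    between = text[end_first:start_second]
    if not between or between[0] != " " or between[-1] != " ":
        return False
    return len(between.split()) <= max_distance


def _composite_spans(text: str, term: CompositeTerm,
                     model: SearchModel) -> list[tuple[int, int]]:
    """Spans covered by a full composite match (any label tuple, any allowed
    part order), found by chaining part matches through the token gap."""
    parts = [model.simple_terms[p] for p in term.parts]
    orders = [parts] if term.ordered else [parts, list(reversed(parts))]
    found: set[tuple[int, int]] = set()
    for order in orders:
        part_spans = []
        for part in order:
            spans = sorted({s for lab in part.labels for s in label_spans_nb(text, lab)})
            part_spans.append(spans)
        # chain: every consecutive pair within the gap
        chains: list[tuple[int, int]] = list(part_spans[0])
        for nxt in part_spans[1:]:
            chains = [
                (s1, e2)
                for s1, e1 in chains
                for s2, e2 in nxt
                if _gap_ok(text, e1, s2, term.max_distance)
            ]
        found.update(chains)
    # outer whole-word boundaries, governed by the end parts' labels, are
    # already enforced per part match; interior boundaries come from the gap
    return sorted(found)


def label_spans_nb(text: str, label: TermLabel) -> list[tuple[int, int]]:
    """Like :func:`label_spans` but with boundary filtering relaxed towards
    whitespace neighbours only where the gap will enforce them.

    For composite chaining the decisive constraint is the whitespace gap;
    a whole-word label still must not sit inside a longer word.
    """
    return label_spans(text, label)


def section_texts(tree: etree._ElementTree, model: SearchModel,
                  node: StructureNode) -> list[str]:
    """Normalized string values of every element at the node's path,
    found by walking parent→child matches from the document root."""
    steps: list[StructureNode] = []
    cur = node
    while cur is not None:
        steps.append(cur)
        cur = cur.parent
    steps.reverse()
    root = tree.getroot()
    rt = steps[0]
    expected = f"{{{rt.namespace}}}{rt.local_name}" if rt.namespace else rt.local_name
    if root.tag != expected:
        return []
    elems = [root]
    for step in steps[1:]:
        tag = f"{{{step.namespace}}}{step.local_name}" if step.namespace else step.local_name
        elems = [child for e in elems for child in e if child.tag == tag]
    return [normalize("".join(e.itertext())) for e in elems]


def concept_matches(tree: etree._ElementTree, concept: SearchConcept,
                    model: SearchModel) -> bool:
    """Existential semantics: at least one section at the concept's node
    contains a term match."""
    term = model.term(concept.term)
    node = model.node_by_id(concept.node)
    for text in section_texts(tree, model, node):
        if isinstance(term, SimpleTerm):
            if any(label_spans(text, lab) for lab in term.labels):
                return True
        else:
            if _composite_spans(text, term, model):
                return True
    return False


def concept_section_spans(tree: etree._ElementTree, concept: SearchConcept,
                          model: SearchModel) -> dict[int, list[tuple[int, int]]]:
    """Match spans per section element (1-based index) — the oracle's view of
    what a snippet record should contain."""
    term = model.term(concept.term)
    node = model.node_by_id(concept.node)
    out: dict[int, list[tuple[int, int]]] = {}
    for idx, text in enumerate(section_texts(tree, model, node), start=1):
        if isinstance(term, SimpleTerm):
            spans = sorted({s for lab in term.labels for s in label_spans(text, lab)})
        else:
            spans = _composite_spans(text, term, model)
        if spans:
            out[idx] = spans
    return out


def _eval(expr: BoolExpr, tree: etree._ElementTree, model: SearchModel) -> bool:
    if isinstance(expr, ConceptRef):
        return concept_matches(tree, model.concepts[expr.concept], model)
    if isinstance(expr, Not):
        return not _eval(expr.operand, tree, model)
    if isinstance(expr, And):
        return all(_eval(op, tree, model) for op in expr.operands)
    if isinstance(expr, Or):
        return any(_eval(op, tree, model) for op in expr.operands)
    raise TypeError(f"unknown expression node {expr!r}")


def oracle_match(doc: Union[str, os.PathLike, etree._ElementTree],
                 query: SearchQuery, model: SearchModel) -> bool:
    """Ground-truth evaluation of one query on one document."""
    tree = doc if isinstance(doc, etree._ElementTree) else etree.parse(str(doc))
    return _eval(query.expr, tree, model)
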