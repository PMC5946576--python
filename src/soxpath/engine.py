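"""Execute compiled queries against an XML corpus and fetch snippets.

The corpus is a directory of well-formed XML files (one document per file;
the file stem is the document id). Compiled XPaths are evaluated with lxml;
the XPath-2.0-style ``matches(text, pattern)`` calls they contain are served
by a registered extension function backed by Python's regex engine.

Retrieved sections are saved as JSON-Lines snippet records plus the raw
section XML fragment, ready for manual review.
"""

from __future__ import annotations

import functools
import json
import os
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional, Union

from lxml import etree

from .codegen import CompiledQuery, term_regexes
from .model import SearchModel, SearchQuery
from .text import normalize


@functools.lru_cache(maxsize=2048)
def _compiled_regex(pattern: str, flags: int = 0) -> re.Pattern:
    return re.compile(pattern, flags)


def _matches_extension(_ctx, value, pattern, flags: str = "") -> bool:
    """XPath ``matches()``: regex search over a string (or first node's value)."""
    if isinstance(value, list):
        value = value[0] if value else ""
    if not isinstance(value, str):
        value = str(value)
    f = re.IGNORECASE if "i" in flags else 0
    return _compiled_regex(pattern, f).search(value) is not None


XPATH_EXTENSIONS = {(None, "matches"): _matches_extension}


@dataclass
class CorpusHandle:
    """A directory corpus: one XML document per ``<doc_id>.xml`` file."""

    root_dir: Path
    doc_ids: list[str]
    prefix_map: dict[str, str] = field(default_factory=dict)

    def path(self, doc_id: str) -> Path:
        return self.root_dir / f"{doc_id}.xml"

    def parse(self, doc_id: str) -> etree._ElementTree:
        return etree.parse(str(self.path(doc_id)))

    def __iter__(self) -> Iterator[str]:
        return iter(self.doc_ids)

    def __len__(self) -> int:
        return len(self.doc_ids)


def open_corpus(root_dir: Union[str, os.PathLike],
                prefix_map: Optional[dict[str, str]] = None) -> CorpusHandle:
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {root}")
    doc_ids = sorted(p.stem for p in root.glob("*.xml"))
    return CorpusHandle(root_dir=root, doc_ids=doc_ids, prefix_map=dict(prefix_map or {}))


@dataclass
class EvaluationResult:
    """Matching document ids (lexicographic) plus per-document read errors."""

    matches: list[str]
    errors: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[str]:
        return iter(self.matches)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.matches

    def __len__(self) -> int:
        return len(self.matches)


def evaluate_query(corpus: CorpusHandle, compiled: CompiledQuery) -> EvaluationResult:
    """Documents whose root satisfies the compiled XPath.

    Malformed XML files are reported in ``errors`` and evaluation continues.
    """
    xp = etree.XPath(compiled.xpath, namespaces=compiled.prefix_map or None,
                     extensions=XPATH_EXTENSIONS)
    matches: list[str] = []
    errors: list[tuple[str, str]] = []
    for doc_id in sorted(corpus.doc_ids):
        try:
            tree = corpus.parse(doc_id)
        except etree.XMLSyntaxError as exc:
            errors.append((doc_id, str(exc)))
            continue
        if xp(tree):
            matches.append(doc_id)
    return EvaluationResult(matches=matches, errors=errors)


# --- Snippet fetching -----------------------------------------------------

@dataclass
class SnippetRecord:
    """One retrieved section with provenance and match offsets."""

    doc_id: str
    query_id: str
    concept_id: str
    section_path: list[tuple[str, str]]  # (namespace, local_name) steps
    section_index: int                   # 1-based among same-path elements
    text: str                            # normalized section text
    matched_spans: list[tuple[str, int, int]]  # (label pattern, start, end)

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False)


def elements_at_path(tree: etree._ElementTree,
                     steps: list[tuple[str, str]]) -> list[etree._Element]:
    """All elements at a root-anchored (namespace, local name) location path."""
    root = tree.getroot()
    ns, name = steps[0]
    tag = f"{{{ns}}}{name}" if ns else name
    if root.tag != tag:
        return []
    current = [root]
    for ns, name in steps[1:]:
        tag = f"{{{ns}}}{name}" if ns else name
        current = [child for elem in current for child in elem if child.tag == tag]
    return current


def regex_spans(text: str, regex: str) -> list[tuple[int, int]]:
    """All match spans, enumerating every start position (overlap-complete)."""
    rx = _compiled_regex(regex)
    spans = []
    for i in range(len(text) + 1):
        m = rx.match(text, i)
        if m and m.end() > m.start():
            spans.append((m.start(), m.end()))
    return sorted(set(spans))


def fetch_snippets(corpus: CorpusHandle, compiled: CompiledQuery, model: SearchModel,
                   out_dir: Union[str, os.PathLike, None] = None,
                   result: Optional[EvaluationResult] = None) -> list[SnippetRecord]:
    """For every matching document, one record per positively-matched section
    element of every positive concept of the query.

    When ``out_dir`` is given, records go to ``snippets.jsonl`` and each raw
    section fragment to ``<out_dir>/<doc_id>/<section_name>.<index>.xml``.
    """
    from .model import resolve_path

    query: SearchQuery = model.queries[compiled.query_id]
    if result is None:
        result = evaluate_query(corpus, compiled)
    positive = model.positive_concept_ids(query.expr)

    records: list[SnippetRecord] = []
    for doc_id in result.matches:
        tree = corpus.parse(doc_id)
        for cid in positive:
            concept = model.concepts[cid]
            steps = resolve_path(model, model.node_by_id(concept.node))
            regexes = term_regexes(model.term(concept.term), model)
            for idx, elem in enumerate(elements_at_path(tree, steps), start=1):
                text = normalize("".join(elem.itertext()))
                spans = [(desc, s, e)
                         for desc, rx in regexes
                         for s, e in regex_spans(text, rx)]
                if spans:
                    records.append(SnippetRecord(
                        doc_id=doc_id, query_id=compiled.query_id, concept_id=cid,
                        section_path=[tuple(q) for q in steps], section_index=idx,
                        text=text, matched_spans=sorted(set(spans))))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "snippets.jsonl", "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(rec.to_json() + "\n")
        for rec in records:
            doc_dir = out / rec.doc_id
            doc_dir.mkdir(exist_ok=True)
            tree = corpus.parse(rec.doc_id)
            elems = elements_at_path(tree, list(rec.section_path))
            elem = elems[rec.section_index - 1]
            name = rec.section_path[-1][1]
            (doc_dir / f"{name}.{rec.section_index}.xml").write_bytes(
                etree.tostring(elem, encoding="utf-8"))
    return records
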