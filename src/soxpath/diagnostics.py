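"""Reviewer-support diagnostics over retrieved snippets.

Two recurring false-positive patterns in section-structured pathology
records are made visible here rather than silently filtered:

* **Enumeration coreference** — sections are often numbered item lists
  ("1. …", "2. …"); when the matches of two co-occurring concepts sit in
  *different* item numbers, they likely describe different specimens and the
  document is a false positive. The report flags such documents but never
  removes them: whether alignment is a hard filter is a reviewer's call.
* **Physical-quantity coreference** — a unit token (g, cm, …) in a section
  need not refer to the concept of interest. Quantity extraction can
  therefore be restricted to values within a word distance of a term match.

Summaries report n/min/max/mean and the population standard deviation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import SearchModel, SimpleTerm
from .oracle import label_spans
from .text import tokenize, token_index_of

logger = logging.getLogger(__name__)

#: An enumeration item starts at a standalone token like ``7.`` or ``12)``.
DEFAULT_ITEM_PATTERN = r"(?:^|(?<= ))(\d{1,2})[.)](?= |$)"


def enumeration_items(text: str, item_pattern: str = DEFAULT_ITEM_PATTERN) \
        -> list[tuple[int, int]]:
    """``(ordinal, start offset)`` of every item marker in a normalized text."""
    return [(int(m.group(1)), m.start()) for m in re.finditer(item_pattern, text)]


def ordinal_at(offset: int, items: list[tuple[int, int]]) -> Optional[int]:
    """Item ordinal containing a character offset; None before the first
    marker (or when the text has no markers)."""
    current = None
    for ordinal, start in items:
        if start <= offset:
            current = ordinal
        else:
            break
    return current


@dataclass
class EnumAlignmentReport:
    doc_id: str
    item_indices: dict[str, list[int]]  # concept_id -> matched item ordinals
    aligned: bool
    details: str


def enum_alignment_report(snippets: Sequence, model: SearchModel,
                          item_pattern: str = DEFAULT_ITEM_PATTERN) \
        -> list[EnumAlignmentReport]:
    """Flag documents whose positive concepts match only in non-intersecting
    enumeration items.

    A concept that (also) matches in a non-enumerated section, or in the text
    before the first item marker, aligns with anything (wildcard). A document
    is misaligned only when at least two concepts are constrained to item
    sets with an empty common intersection.
    """
    by_doc: dict[str, list] = {}
    for rec in snippets:
        by_doc.setdefault(rec.doc_id, []).append(rec)

    reports: list[EnumAlignmentReport] = []
    for doc_id in sorted(by_doc):
        ordinals: dict[str, set[int]] = {}
        wildcard: dict[str, bool] = {}
        for rec in by_doc[doc_id]:
            items = enumeration_items(rec.text, item_pattern)
            cid = rec.concept_id
            ordinals.setdefault(cid, set())
            wildcard.setdefault(cid, False)
            if not items:
                wildcard[cid] = True
                continue
            for _desc, start, _end in rec.matched_spans:
                o = ordinal_at(start, items)
                if o is None:
                    wildcard[cid] = True
                else:
                    ordinals[cid].add(o)

        constrained = {c: s for c, s in ordinals.items() if s and not wildcard[c]}
        if len(constrained) >= 2:
            common = set.intersection(*constrained.values())
            aligned = bool(common)
            details = (f"common item(s): {sorted(common)}" if aligned else
                       "positive concepts match in disjoint enumeration items: "
                       + "; ".join(f"{c} in {sorted(s)}" for c, s in sorted(constrained.items())))
        else:
            aligned = True
            details = "fewer than two item-constrained concepts"
        reports.append(EnumAlignmentReport(
            doc_id=doc_id, aligned=aligned, details=details,
            item_indices={c: sorted(s) for c, s in sorted(ordinals.items())}))
    return reports


# --- Physical quantities --------------------------------------------------

NUMBER_RE = re.compile(r"^\d+(?:[.,]\d+)?$")
_TRAIL_PUNCT = ".,;:!?)]"
_LEAD_PUNCT = "([\"'"


def _strip_punct(token: str) -> str:
    return token.lstrip(_LEAD_PUNCT).rstrip(_TRAIL_PUNCT)


def extract_quantities(snippets: Sequence, unit_pattern: str,
                       proximity_term: Optional[SimpleTerm] = None,
                       max_distance: int = 0) -> list[tuple[str, float, str]]:
    """``(doc_id, value, unit)`` for every number+unit token pair found.

    A pair is a number token (decimal comma or point) immediately followed by
    a token matching ``unit_pattern`` entirely (trailing punctuation
    ignored). With ``proximity_term``, only pairs whose number token lies
    within ``max_distance`` tokens of a term match are kept.
    """
    unit_rx = re.compile(unit_pattern)
    out: list[tuple[str, float, str]] = []
    seen: set[tuple] = set()
    for rec in snippets:
        tokens = tokenize(rec.text)
        term_token_idx: set[int] = set()
        if proximity_term is not None:
            for lab in proximity_term.labels:
                for s, _e in label_spans(rec.text, lab):
                    term_token_idx.add(token_index_of(s, tokens))
        for i in range(len(tokens) - 1):
            num_tok = _strip_punct(tokens[i][0])
            unit_tok = _strip_punct(tokens[i + 1][0])
            if not NUMBER_RE.match(num_tok) or not unit_rx.fullmatch(unit_tok):
                continue
            key = (rec.doc_id, tuple(map(tuple, rec.section_path)),
                   rec.section_index, tokens[i][1])
            if key in seen:
                continue
            if proximity_term is not None:
                # tokens strictly between the number and the nearest term match
                if not any(abs(i - j) - 1 <= max_distance and i != j
                           for j in term_token_idx):
                    continue
            seen.add(key)
            try:
                value = float(num_tok.replace(",", "."))
            except ValueError:  # pragma: no cover - NUMBER_RE should prevent
                logger.warning("skipping non-parsing quantity %r in %s", num_tok, rec.doc_id)
                continue
            out.append((rec.doc_id, value, unit_tok))
    return out


@dataclass
class QuantitySummary:
    unit: str
    values: list[float]
    n: int
    min: Optional[float]
    max: Optional[float]
    mean: Optional[float]
    sd: Optional[float]

    def as_dict(self) -> dict:
        return {"unit": self.unit, "n": self.n, "min": self.min, "max": self.max,
                "mean": self.mean, "sd": self.sd}


def summarize_quantities(values: Sequence[float], unit: str) -> QuantitySummary:
    """n, min, max, arithmetic mean and population standard deviation.

    An empty input yields ``n = 0`` with the statistics marked undefined
    (``None``).
    """
    vals = [float(v) for v in values]
    if not vals:
        return QuantitySummary(unit=unit, values=[], n=0,
                               min=None, max=None, mean=None, sd=None)
    arr = np.asarray(vals, dtype=float)
    return QuantitySummary(
        unit=unit, values=vals, n=len(vals),
        min=float(arr.min()), max=float(arr.max()),
        mean=float(arr.mean()), sd=float(arr.std(ddof=0)))
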