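"""Shared text normalization and tokenization.

One tokenizer serves the engine, the oracle and the diagnostics so that
token-counted word distances mean the same thing everywhere: text is
whitespace-normalized exactly like XPath ``normalize-space`` (XML whitespace
collapsed to single spaces, ends stripped) and tokens are the maximal
non-space runs, punctuation left attached.
"""

from __future__ import annotations

import re

_XML_WS = re.compile(r"[ \t\r\n]+")


def normalize(text: str) -> str:
    """Collapse XML whitespace to single spaces and strip the ends."""
    return _XML_WS.sub(" ", text).strip()


def tokenize(normalized: str) -> list[tuple[str, int, int]]:
    """``(token, start, end)`` triples over an already-normalized string."""
    out = []
    pos = 0
    for tok in normalized.split(" ") if normalized else []:
        out.append((tok, pos, pos + len(tok)))
        pos += len(tok) + 1
    return out


def token_index_of(offset: int, tokens: list[tuple[str, int, int]]) -> int:
    """Index of the token containing (or starting at) a character offset."""
    for i, (_, s, e) in enumerate(tokens):
        if s <= offset <= e:
            return i
    raise ValueError(f"offset {offset} outside tokenized text")
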