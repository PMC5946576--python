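"""Shared fixtures: hand-written Q1 models and small corpus builders."""

from __future__ import annotations

from pathlib import Path

import pytest

from soxpath import SearchModel, load_model
from soxpath.codegen import build_prefix_map
from soxpath.engine import open_corpus
from soxpath.synth import bundled_model, render_document

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def q1_native() -> SearchModel:
    return load_model(DATA / "q1.yaml")


@pytest.fixture(scope="session")
def q1_owl() -> SearchModel:
    return load_model(DATA / "q1.ttl")


@pytest.fixture(scope="session")
def pathology_model() -> SearchModel:
    return bundled_model()


class CorpusBuilder:
    """Write documents with chosen per-section texts against a model's
    structure tree, then open the directory as a corpus."""

    def __init__(self, model: SearchModel, root: Path):
        self.model = model
        self.root = root
        self.prefix_map = build_prefix_map(model)
        root.mkdir(parents=True, exist_ok=True)

    def add(self, doc_id: str, **section_texts: str) -> None:
        payload = render_document(self.model.structure, section_texts, self.prefix_map)
        (self.root / f"{doc_id}.xml").write_bytes(payload)

    def open(self):
        return open_corpus(self.root, prefix_map=self.prefix_map)


@pytest.fixture
def corpus_builder(tmp_path, pathology_model):
    def make(model: SearchModel = None, subdir: str = "corpus") -> CorpusBuilder:
        return CorpusBuilder(model or pathology_model, tmp_path / subdir)
    return make


def enumerated_text(items: dict[int, str], n_items: int, filler: str = "Befund") -> str:
    """An n-item enumeration in normalized (single-space) form, item texts
    taken from ``items`` by ordinal."""
    lines = []
    for i in range(1, n_items + 1):
        lines.append(f"{i}. {items.get(i, filler)}")
    return " ".join(lines)
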