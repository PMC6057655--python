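"""Shared fixtures: tiny vocabularies, document builders, generated corpora."""

from __future__ import annotations

import pytest

from phir import (
    Concept,
    DocumentStore,
    PhirConfig,
    RegisteredDocument,
    RegistrationEntry,
    SearchIndex,
    build_index,
    fixtures,
)
from phir.annotator import Annotation


@pytest.fixture
def small_ontology():
    """Hand-written vocabulary with synonyms, cross-language terms, and an
    ambiguous term shared by two concepts."""
    return build_index(
        [
            Concept("C1", "breast cancer", "en"),
            Concept("C1", "Brustkrebs", "de"),
            Concept("C1", "cancro al seno", "it"),
            Concept("C2", "tumor", "en"),
            Concept("C2", "Tumor", "de"),
            Concept("C3", "chemotherapy", "en"),
            Concept("C4", "asthma", "en"),
            Concept("C5", "asthma", "en"),  # ambiguity: same term, two ids
        ]
    )


def make_doc(
    doc_id: str,
    text: str = "",
    title: str | None = None,
    doc_type: str = "text",
    language: str = "en",
    tags: tuple[str, ...] = (),
    concepts: tuple[str, ...] = (),
) -> RegisteredDocument:
    entry = RegistrationEntry(
        url=f"http://example.org/{doc_id}",
        title=title if title is not None else f"title {doc_id}",
        doc_type=doc_type,
        language=language,
        tags=tags,
    )
    annotations = tuple(
        Annotation(concept_id=c, matched_term=c, source_text=c, similarity=1.0)
        for c in concepts
    )
    return RegisteredDocument(
        doc_id=doc_id, entry=entry, text=text, annotations=annotations, registered_at=0.0
    )


@pytest.fixture
def doc_factory():
    return make_doc


@pytest.fixture
def indexed_corpus():
    """Six-document mixed text/video corpus with known contents."""
    docs = [
        make_doc("d1", "cancer treatment options and therapy plans", concepts=("C1",)),
        make_doc("d2", "weather report for the weekend"),
        make_doc("d3", "chemotherapy side effects and cancer care", concepts=("C1", "C3")),
        make_doc("d4", "", doc_type="video", tags=("chemotherapy",), concepts=("C3",)),
        make_doc("d5", "asthma and allergy management", concepts=("C4",)),
        make_doc("d6", "surgery recovery handbook"),
    ]
    index = SearchIndex()
    store = DocumentStore()
    for d in docs:
        index.add_document(d)
        store.put(d)
    return index, store, docs


@pytest.fixture
def generated_corpus(tmp_path):
    """Generated 20-doc corpus with exact plants plus its manifests."""
    onto_manifest = fixtures.generate_ontology(40, ["en"], seed=11, out_dir=tmp_path)
    corpus_manifest = fixtures.generate_corpus(
        20, onto_manifest, mutation_rate=0.0, seed=12, out_dir=tmp_path
    )
    return tmp_path, onto_manifest, corpus_manifest
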