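"""Inverted index with field-weighted BM25 scoring.

The index holds four fields per document — title, content, tags, and the
concept identifiers attached by the annotator — each with its own postings,
length statistics, and weight.  Title, content and tag text is tokenized
and lemmatized with the same pipeline used for annotation, so a query term
meets documents in the same normalized space; concept ids are indexed
verbatim.

Scoring is standard BM25 per field, summed with field weights:

    score(q, d) = sum_f w_f * sum_{t in q} idf(t, f)
                  * tf * (k1 + 1) / (tf + k1 * (1 - b + b * len_f(d) / avglen_f))

with idf(t, f) = ln(1 + (N - df + 0.5) / (df + 0.5)), N the total document
count and df the number of documents whose field f contains t.  Defaults
k1 = 1.2, b = 0.75.  Ties are broken by doc_id so rankings are
deterministic.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .annotator import RegisteredDocument
from .config import DEFAULT_CONFIG, PhirConfig, SUPPORTED_LANGUAGES
from .textproc import Tagger, get_tagger, tokenize

FIELDS = ("title", "content", "tags", "concepts")


class BlankQueryError(ValueError):
    """Query is empty after normalization."""


@dataclass(frozen=True)
class ScoredHit:
    """A document matched by a search, with its BM25 score and the fields
    that contributed."""

    doc_id: str
    score: float
    matched_fields: frozenset[str] = frozenset()


def _lemmas(text: str, language: str, tagger: Tagger) -> list[str]:
    """Index/query analysis: lemma of every alphabetic token (all parts of
    speech — queries are not restricted to nouns), lowercased."""
    if language in SUPPORTED_LANGUAGES:
        return [r.lemma for r in tagger.tag(text, language)]
    return [s.lower() for s, _ in tokenize(text)]


class SearchIndex:
    """In-memory inverted index over registered documents."""

    def __init__(self, config: PhirConfig = DEFAULT_CONFIG, tagger: Tagger | None = None):
        self.config = config
        self._tagger = tagger or get_tagger()
        # field -> term -> {doc_id: term frequency}
        self.postings: dict[str, dict[str, dict[str, int]]] = {
            f: defaultdict(dict) for f in FIELDS
        }
        # field -> doc_id -> token count
        self.field_lengths: dict[str, dict[str, int]] = {f: {} for f in FIELDS}
        self.doc_ids: set[str] = set()
        self.doc_language: dict[str, str] = {}

    # -- construction -------------------------------------------------------

    def _field_tokens(self, doc: RegisteredDocument) -> dict[str, list[str]]:
        lang = doc.entry.language
        return {
            "title": _lemmas(doc.entry.title, lang, self._tagger),
            "content": _lemmas(doc.text, lang, self._tagger) if doc.text else [],
            "tags": [
                lemma
                for tag in doc.entry.tags
                for lemma in _lemmas(tag, lang, self._tagger)
            ],
            "concepts": doc.concept_ids(),
        }

    def add_document(self, doc: RegisteredDocument) -> str:
        """Index (or re-index, replacing postings) one document."""
        if doc.doc_id in self.doc_ids:
            self.remove_document(doc.doc_id)
        for fname, tokens in self._field_tokens(doc).items():
            counts = Counter(tokens)
            self.field_lengths[fname][doc.doc_id] = sum(counts.values())
            for term, tf in counts.items():
                self.postings[fname][term][doc.doc_id] = tf
        self.doc_ids.add(doc.doc_id)
        self.doc_language[doc.doc_id] = doc.entry.language
        return doc.doc_id

    def remove_document(self, doc_id: str) -> None:
        if doc_id not in self.doc_ids:
            return
        for fname in FIELDS:
            self.field_lengths[fname].pop(doc_id, None)
            empty = [t for t, docs in self.postings[fname].items() if docs.pop(doc_id, None) is not None and not docs]
            for t in empty:
                del self.postings[fname][t]
        self.doc_ids.discard(doc_id)
        self.doc_language.pop(doc_id, None)

    def add_all(self, docs: Sequence[RegisteredDocument]) -> None:
        for doc in docs:
            self.add_document(doc)

    # -- statistics ---------------------------------------------------------

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def document_frequency(self, term: str, field_name: str) -> int:
        return len(self.postings[field_name].get(term, {}))

    def _avg_field_length(self, field_name: str) -> float:
        lengths = self.field_lengths[field_name]
        if not lengths:
            return 0.0
        return sum(lengths.values()) / self.n_docs

    # -- scoring ------------------------------------------------------------

    def bm25_score(
        self,
        query_terms: Sequence[str],
        doc_id: str,
        field_weights: dict[str, float] | None = None,
        k1: float | None = None,
        b: float | None = None,
    ) -> float:
        """Field-weighted BM25 score of one document for analyzed query
        terms.  Raises ``KeyError`` for an unknown doc_id."""
        if doc_id not in self.doc_ids:
            raise KeyError(f"unknown document {doc_id!r}")
        weights = field_weights if field_weights is not None else self.config.field_weights
        k1 = self.config.bm25_k1 if k1 is None else k1
        b = self.config.bm25_b if b is None else b
        n = self.n_docs
        score = 0.0
        for fname, weight in weights.items():
            if weight == 0.0 or fname not in FIELDS:
                continue
            avgdl = self._avg_field_length(fname)
            if avgdl == 0.0:
                continue
            dl = self.field_lengths[fname].get(doc_id, 0)
            for term in query_terms:
                docs = self.postings[fname].get(term)
                if not docs:
                    continue
                tf = docs.get(doc_id, 0)
                if tf == 0:
                    continue
                df = len(docs)
                idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
                score += (
                    weight
                    * idf
                    * tf
                    * (k1 + 1.0)
                    / (tf + k1 * (1.0 - b + b * dl / avgdl))
                )
        return score

    def matched_fields(self, query_terms: Sequence[str], doc_id: str) -> frozenset[str]:
        return frozenset(
            fname
            for fname in FIELDS
            if any(doc_id in self.postings[fname].get(t, {}) for t in query_terms)
        )

    def analyze_query(self, query: str, language: str) -> list[str]:
        terms = _lemmas(query, language, self._tagger)
        if not terms:
            raise BlankQueryError("query is blank after analysis")
        return terms

    def search(self, query: str, language: str = "en", top_k: int = 20) -> list[ScoredHit]:
        """Ranked hits for a free-text query.

        The query goes through the same lemmatization as documents; hits are
        sorted by score descending with doc_id tie-breaks, only documents
        with positive score are returned, at most ``top_k`` of them.
        """
        if not query or not query.strip():
            raise BlankQueryError("query must be non-blank")
        terms = self.analyze_query(query, language)
        return self.search_terms(terms, top_k=top_k)

    def search_terms(self, terms: Sequence[str], top_k: int | None = None) -> list[ScoredHit]:
        """Ranked hits for pre-analyzed terms (used for concept-id queries)."""
        candidates: set[str] = set()
        for fname in FIELDS:
            if self.config.field_weights.get(fname, 0.0) == 0.0:
                continue
            for term in terms:
                candidates.update(self.postings[fname].get(term, {}))
        hits = []
        for doc_id in candidates:
            score = self.bm25_score(terms, doc_id)
            if score > 0.0:
                hits.append(
                    ScoredHit(
                        doc_id=doc_id,
                        score=score,
                        matched_fields=self.matched_fields(terms, doc_id),
                    )
                )
        hits.sort(key=lambda h: (-h.score, h.doc_id))
        return hits if top_k is None else hits[:top_k]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "postings": {
                f: {t: docs for t, docs in terms.items()}
                for f, terms in self.postings.items()
            },
            "field_lengths": self.field_lengths,
            "doc_ids": sorted(self.doc_ids),
            "doc_language": self.doc_language,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, config: PhirConfig = DEFAULT_CONFIG) -> "SearchIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        index = cls(config=config)
        for f, terms in payload["postings"].items():
            index.postings[f] = defaultdict(dict, {t: dict(d) for t, d in terms.items()})
        index.field_lengths = {f: dict(v) for f, v in payload["field_lengths"].items()}
        index.doc_ids = set(payload["doc_ids"])
        index.doc_language = dict(payload.get("doc_language", {}))
        return index
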