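"""Expert registration pipeline and concept matcher.

An expert registers a web resource through a small form (URL, title, type,
language, optional tags).  For text resources the same-domain crawler pulls
in the whole site; each page's visible text is lemmatized and its noun
lemmas — plus short multiword windows, so terms like "breast cancer" are
reachable — are matched against the vocabulary by normalized Levenshtein
similarity.  Matches at or above the threshold tau become annotations
stored with the document; expert tags are matched the same way and labelled
with their own origin.

The similarity metric is ``1 - levenshtein(a, b) / max(|a|, |b|)`` on
normalized strings: 1.0 exactly for normalized equality, symmetric, and
cheap to bound (a banded DP with an early cutoff skips hopeless pairs).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .config import DEFAULT_CONFIG, PhirConfig, SUPPORTED_LANGUAGES, logger
from .crawler import CrawlError, FetchedPage, Fetcher, HttpFetcher, crawl, normalize_url
from .ontology import OntologyIndex, normalize_term
from .textproc import LemmaRecord, Tagger, UnsupportedContentError, extract_text, get_tagger

ANNOTATION_ORIGINS = ("content", "tag")
DOC_TYPES = ("text", "video")


class RegistrationError(RuntimeError):
    """The resource could not be registered (e.g. unreachable URL)."""


# ---------------------------------------------------------------------------
# string similarity
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Edit distance by banded dynamic programming.

    With ``max_dist`` set, computation is confined to a diagonal band and
    returns ``max_dist + 1`` as soon as the true distance is provably above
    the bound — the caller only needs "too far" in that case.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    if la > lb:  # keep the inner loop over the shorter string
        a, b, la, lb = b, a, lb, la
    big = la + lb  # sentinel > any real distance
    prev = list(range(la + 1))
    cur = [0] * (la + 1)
    for j in range(1, lb + 1):
        bj = b[j - 1]
        if max_dist is None:
            lo, hi = 1, la
            cur[0] = j
        else:
            lo = max(1, j - max_dist)
            hi = min(la, j + max_dist)
            cur[0] = j if j <= max_dist else big
            if lo > 1:
                cur[lo - 1] = big
        best = cur[lo - 1]
        for i in range(lo, hi + 1):
            cost = 0 if a[i - 1] == bj else 1
            v = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + cost)
            cur[i] = v
            if v < best:
                best = v
        if hi < la:
            cur[hi + 1 :] = [big] * (la - hi)
        if max_dist is not None and best > max_dist:
            return max_dist + 1
        prev, cur = cur, prev
    d = prev[la]
    if max_dist is not None and d > max_dist:
        return max_dist + 1
    return d


def string_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1] on normalized strings.

    1.0 iff the normalized strings are equal; symmetric.  Raises
    ``ValueError`` when either side is empty after normalization.
    """
    na, nb = normalize_term(a), normalize_term(b)
    if not na or not nb:
        raise ValueError("string_similarity requires non-empty strings")
    if na == nb:
        return 1.0
    return 1.0 - levenshtein(na, nb) / max(len(na), len(nb))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Annotation:
    """A vocabulary concept attached to a document: which term matched,
    what source string it matched against, how similar, and whether it came
    from the document content or an expert tag."""

    concept_id: str
    matched_term: str
    source_text: str
    similarity: float
    origin: str = "content"

    def __post_init__(self) -> None:
        if self.origin not in ANNOTATION_ORIGINS:
            raise ValueError(f"origin {self.origin!r} not in {ANNOTATION_ORIGINS}")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must be in [0, 1]")


def match_concepts(
    candidates: Sequence[str],
    index: OntologyIndex,
    language: str,
    threshold: float = DEFAULT_CONFIG.similarity_threshold,
    origin: str = "content",
) -> list[Annotation]:
    """Match candidate strings against the vocabulary's language bucket.

    Every (candidate, term) pair with similarity >= ``threshold`` yields an
    annotation; per (candidate, concept) only the best-similarity term is
    kept.  Output is sorted by similarity descending, ties broken by
    concept_id then matched term.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    bucket = index.terms_in_language(language)
    if not bucket:
        return []
    best: dict[tuple[str, str], Annotation] = {}
    for cand in candidates:
        nc = normalize_term(cand)
        if not nc:
            continue
        for term, concepts in bucket.items():
            # distance bound implied by the similarity threshold
            maxlen = max(len(nc), len(term))
            max_dist = int((1.0 - threshold) * maxlen)
            if abs(len(nc) - len(term)) > max_dist:
                continue
            if nc == term:
                sim = 1.0
            else:
                d = levenshtein(nc, term, max_dist=max_dist)
                if d > max_dist:
                    continue
                sim = 1.0 - d / maxlen
            if sim < threshold:
                continue
            for concept in concepts:
                key = (cand, concept.concept_id)
                prior = best.get(key)
                if prior is None or sim > prior.similarity:
                    best[key] = Annotation(
                        concept_id=concept.concept_id,
                        matched_term=concept.term,
                        source_text=cand,
                        similarity=sim,
                        origin=origin,
                    )
    return sorted(
        best.values(), key=lambda a: (-a.similarity, a.concept_id, a.matched_term)
    )


def candidate_strings(records: Sequence[LemmaRecord]) -> list[str]:
    """Matchable strings from tagged text: each noun lemma, plus sliding
    windows of 2-3 consecutive token lemmas containing at least one noun
    (multiword vocabulary terms are otherwise unreachable)."""
    out: list[str] = []
    seen: set[str] = set()

    def push(s: str) -> None:
        if s and s not in seen:
            seen.add(s)
            out.append(s)

    for rec in records:
        if rec.pos == "NOUN":
            push(rec.lemma)
    for width in (2, 3):
        for i in range(len(records) - width + 1):
            window = records[i : i + width]
            if any(r.pos == "NOUN" for r in window):
                push(" ".join(r.lemma for r in window))
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationEntry:
    """The expert's form entry for one web resource."""

    url: str
    title: str
    doc_type: str
    language: str
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.title.strip():
            raise ValueError("title must be non-empty")
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"doc_type {self.doc_type!r} not in {DOC_TYPES}")
        if self.language not in SUPPORTED_LANGUAGES:
            raise ValueError(f"language {self.language!r} not supported")


def doc_id_for(url: str) -> str:
    """Stable document identifier: hash of the canonical URL."""
    canon = normalize_url(url) or url
    return hashlib.sha1(canon.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class RegisteredDocument:
    doc_id: str
    entry: RegistrationEntry
    text: str
    annotations: tuple[Annotation, ...]
    registered_at: float

    def to_json_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "url": self.entry.url,
            "title": self.entry.title,
            "type": self.entry.doc_type,
            "language": self.entry.language,
            "tags": list(self.entry.tags),
            "text": self.text,
            "annotations": [
                {
                    "concept_id": a.concept_id,
                    "matched_term": a.matched_term,
                    "source_text": a.source_text,
                    "similarity": a.similarity,
                    "origin": a.origin,
                }
                for a in self.annotations
            ],
            "registered_at": self.registered_at,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegisteredDocument":
        entry = RegistrationEntry(
            url=d["url"],
            title=d["title"],
            doc_type=d["type"],
            language=d["language"],
            tags=tuple(d.get("tags", [])),
        )
        return cls(
            doc_id=d["doc_id"],
            entry=entry,
            text=d.get("text", ""),
            annotations=tuple(Annotation(**a) for a in d.get("annotations", [])),
            registered_at=d.get("registered_at", 0.0),
        )

    def concept_ids(self) -> list[str]:
        return sorted({a.concept_id for a in self.annotations})


def _dedupe_annotations(
    annotations: Iterable[Annotation], cap: int
) -> tuple[Annotation, ...]:
    """Keep the best annotation per (concept_id, origin), then the top
    ``cap`` by similarity."""
    best: dict[tuple[str, str], Annotation] = {}
    for a in annotations:
        key = (a.concept_id, a.origin)
        prior = best.get(key)
        if prior is None or a.similarity > prior.similarity:
            best[key] = a
    ranked = sorted(
        best.values(), key=lambda a: (-a.similarity, a.concept_id, a.origin)
    )
    return tuple(ranked[:cap])


def annotate_document(
    text: str,
    tags: Sequence[str],
    ontology: OntologyIndex,
    language: str,
    config: PhirConfig = DEFAULT_CONFIG,
    tagger: Tagger | None = None,
) -> tuple[Annotation, ...]:
    """Content-origin annotations from the text plus tag-origin annotations
    from the expert tags, deduplicated and capped."""
    from .textproc import lemmatize_nouns

    tagger = tagger or get_tagger()
    anns: list[Annotation] = []
    if text:
        if language in SUPPORTED_LANGUAGES:
            records = tagger.tag(text, language)
        else:  # degraded whitespace mode: every token is a candidate noun
            records = lemmatize_nouns(text, language)
        anns.extend(
            match_concepts(
                candidate_strings(records),
                ontology,
                language,
                threshold=config.similarity_threshold,
                origin="content",
            )
        )
    cleaned_tags = [t for t in tags if t.strip()]
    if cleaned_tags:
        anns.extend(
            match_concepts(
                cleaned_tags,
                ontology,
                language,
                threshold=config.similarity_threshold,
                origin="tag",
            )
        )
    return _dedupe_annotations(anns, cap=config.max_annotations_per_doc)


class DocumentStore:
    """Registered-document store, persisted as JSON-lines (one document per
    line, fixed field names)."""

    def __init__(self) -> None:
        self._docs: dict[str, RegisteredDocument] = {}

    def __len__(self) -> int:
        return len(self._docs)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def get(self, doc_id: str) -> RegisteredDocument | None:
        return self._docs.get(doc_id)

    def put(self, doc: RegisteredDocument) -> None:
        self._docs[doc.doc_id] = doc

    def documents(self) -> list[RegisteredDocument]:
        return [self._docs[k] for k in sorted(self._docs)]

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for doc in self.documents():
                fh.write(json.dumps(doc.to_json_dict(), ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DocumentStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    store.put(RegisteredDocument.from_json_dict(json.loads(line)))
        return store


def register(
    entry: RegistrationEntry,
    ontology: OntologyIndex,
    store: DocumentStore,
    config: PhirConfig = DEFAULT_CONFIG,
    fetcher: Fetcher | None = None,
    crawl_site: bool = True,
    tagger: Tagger | None = None,
    now: float | None = None,
) -> list[RegisteredDocument]:
    """Register a resource: fetch, (for text) crawl the same-domain site,
    extract and annotate text, and store one document per page.

    Video resources are registered from the form entry alone, with
    tag-derived annotations only.  Re-registering a URL replaces the prior
    record (the store keys on the canonical-URL hash).

    Raises
    ------
    RegistrationError
        When the seed URL is unreachable; nothing is stored.
    """
    if fetcher is None:
        fetcher = HttpFetcher()
    timestamp = time.time() if now is None else now
    registered: list[RegisteredDocument] = []

    if entry.doc_type == "video":
        annotations = annotate_document(
            "", entry.tags, ontology, entry.language, config=config, tagger=tagger
        )
        doc = RegisteredDocument(
            doc_id=doc_id_for(entry.url),
            entry=entry,
            text="",
            annotations=annotations,
            registered_at=timestamp,
        )
        store.put(doc)
        return [doc]

    try:
        pages = crawl(
            entry.url,
            fetcher=fetcher,
            max_pages=config.max_pages if crawl_site else 1,
            max_depth=config.max_depth if crawl_site else 0,
            delay_seconds=0.0,
        )
    except CrawlError as exc:
        raise RegistrationError(str(exc)) from exc

    for page in pages:
        text = ""
        try:
            text = extract_text(page.content, page.content_type)
        except UnsupportedContentError:
            logger.warning(
                "unsupported content type %r at %s; tag annotations only",
                page.content_type,
                page.url,
            )
        page_entry = replace(entry, url=page.url)  # children inherit form metadata
        annotations = annotate_document(
            text, entry.tags, ontology, entry.language, config=config, tagger=tagger
        )
        doc = RegisteredDocument(
            doc_id=doc_id_for(page.url),
            entry=page_entry,
            text=text,
            annotations=annotations,
            registered_at=timestamp,
        )
        store.put(doc)
        registered.append(doc)
    return registered
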