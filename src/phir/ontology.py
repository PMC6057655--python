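"""Concept vocabulary store.

Loads plain TSV concept tables (``concept_id<TAB>term<TAB>language``) that
stand in for licensed clinical vocabularies (SNOMED CT, LOINC, RXTerms) in
English, German, and Italian.  Terms are normalized by Unicode case-folding
plus whitespace collapse; diacritics are preserved because they are
meaningful in German and Italian.  An optional OBO reader maps ``[Term]``
stanzas (id / name / synonym) onto the same row model.
"""

from __future__ import annotations

import unicodedata
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .config import SUPPORTED_LANGUAGES, logger


class OntologyError(ValueError):
    """Raised for unusable vocabulary input (missing file, zero valid rows)."""


class UnsupportedLanguageError(ValueError):
    """Raised when a language code is outside the supported set."""


def normalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace; NFC-normalize unicode."""
    return " ".join(unicodedata.normalize("NFC", term).casefold().split())


@dataclass(frozen=True)
class Concept:
    """One matchable vocabulary entry: an identifier bound to a surface term
    in one language.  The same concept_id may carry many terms (synonyms,
    translations), each its own :class:`Concept` row."""

    concept_id: str
    term: str
    language: str
    source: str = "SNOMEDCT"

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("concept term must be non-empty")
        if self.language not in SUPPORTED_LANGUAGES:
            raise UnsupportedLanguageError(
                f"language {self.language!r} not in {SUPPORTED_LANGUAGES}"
            )

    @property
    def normalized_term(self) -> str:
        return normalize_term(self.term)


@dataclass
class OntologyIndex:
    """In-memory vocabulary with per-language lookup buckets."""

    concepts: set[Concept] = field(default_factory=set)
    #: language -> normalized term -> concepts carrying that term
    by_language: dict[str, dict[str, set[Concept]]] = field(
        default_factory=lambda: defaultdict(dict)
    )
    skipped_rows: int = 0

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts)

    def add(self, concept: Concept) -> bool:
        """Insert one concept; exact-triple duplicates are dropped. Returns
        True when the concept was new."""
        if concept in self.concepts:
            return False
        self.concepts.add(concept)
        bucket = self.by_language[concept.language]
        bucket.setdefault(concept.normalized_term, set()).add(concept)
        return True

    def languages(self) -> set[str]:
        return {c.language for c in self.concepts}

    def terms_in_language(self, language: str) -> dict[str, set[Concept]]:
        if language not in SUPPORTED_LANGUAGES:
            raise UnsupportedLanguageError(f"unsupported language {language!r}")
        return self.by_language.get(language, {})

    def lookup_exact(self, term: str, language: str) -> set[Concept]:
        """All concepts whose normalized term equals the normalized input in
        the given language; empty set when none."""
        if language not in SUPPORTED_LANGUAGES:
            raise UnsupportedLanguageError(f"unsupported language {language!r}")
        return set(self.by_language.get(language, {}).get(normalize_term(term), set()))

    def to_tsv(self, path: str | Path) -> None:
        """Write the store back out as a three-column TSV (round-trippable)."""
        rows = sorted(
            (c.concept_id, c.term, c.language) for c in self.concepts
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("concept_id\tterm\tlanguage\n")
            for cid, term, lang in rows:
                fh.write(f"{cid}\t{term}\t{lang}\n")


def lookup_exact(index: OntologyIndex, term: str, language: str) -> set[Concept]:
    return index.lookup_exact(term, language)


def load_concept_table(
    path: str | Path,
    default_language: str = "en",
    source: str = "SNOMEDCT",
) -> OntologyIndex:
    """Load a TSV concept table into an :class:`OntologyIndex`.

    Expected columns: ``concept_id``, ``term``, optional ``language``
    (``default_language`` applies when absent or blank).  Malformed rows are
    skipped with a warning and counted on ``index.skipped_rows``.

    Raises
    ------
    OntologyError
        If the file is missing or yields zero valid rows — registration
        cannot proceed without a vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise OntologyError(f"concept table not found: {path}")

    index = OntologyIndex()
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise OntologyError(f"empty concept table: {path}")

    header = lines[0].rstrip("\n").split("\t")
    has_header = header and header[0].strip().lower() == "concept_id"
    body = lines[1:] if has_header else lines

    for lineno, line in enumerate(body, start=2 if has_header else 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        try:
            cid = cols[0].strip()
            term = cols[1].strip() if len(cols) > 1 else ""
            lang = cols[2].strip() if len(cols) > 2 and cols[2].strip() else default_language
            if not cid or not term:
                raise ValueError("missing concept_id or term")
            concept = Concept(cid, term, lang, source=source)
        except (IndexError, ValueError) as exc:
            index.skipped_rows += 1
            logger.warning("skipping malformed concept row %d: %s (%s)", lineno, line, exc)
            continue
        index.add(concept)

    if len(index) == 0:
        raise OntologyError(f"no valid concept rows in {path}")
    return index


def load_obo(
    path: str | Path,
    language: str = "en",
    source: str = "OBO",
) -> OntologyIndex:
    """Read an OBO ontology, mapping each term's ``name`` and ``synonym``
    lines to concept rows in a single language."""
    import obonet

    graph = obonet.read_obo(str(path))
    index = OntologyIndex()
    for node_id, data in graph.nodes(data=True):
        name = data.get("name")
        if name:
            index.add(Concept(node_id, name, language, source=source))
        for syn in data.get("synonym", []):
            # obonet keeps the raw line: "text" SCOPE [xrefs]
            if syn.startswith('"') and '"' in syn[1:]:
                text = syn[1 : syn.index('"', 1)]
                if text.strip():
                    index.add(Concept(node_id, text, language, source=source))
    if len(index) == 0:
        raise OntologyError(f"no terms found in OBO file {path}")
    return index


def build_index(concepts: Iterable[Concept]) -> OntologyIndex:
    """Convenience constructor from an iterable of concepts."""
    index = OntologyIndex()
    for c in concepts:
        index.add(c)
    return index
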