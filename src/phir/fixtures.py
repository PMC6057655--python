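"""Deterministic synthetic-data generators and their manifests.

Everything the test suite (and the acceptance checks) need is generated
here from a seed: toy multilingual concept tables, HTML corpora with
planted concept mentions (exact or single-edit misspelled), small linkable
websites with on- and off-domain links, and simulated user sessions.  Each
generator writes plain files (TSV, HTML, JSON) consumed through the
package's normal readers, and returns a manifest that fully determines the
generated artifacts — the manifest, never the generator internals, is the
oracle other tests consult.

Generated language is pronounceable nonsense, not clinical prose: what is
controlled is exactly the structure the pipeline keys on (which terms occur
where, which links exist, which events were emitted).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

#: filler words that never collide with generated terms (too short or
#: containing characters the term generator never emits)
_FILLER = (
    "the on with about from info page more here also some other very",
    "der die und mit von für auf mehr hier auch sehr über eine",
    "il la e con di per su più qui anche molto una",
)
_FILLER_BY_LANG = {"en": _FILLER[0].split(), "de": _FILLER[1].split(), "it": _FILLER[2].split()}


def _word(rng: random.Random, syllables: int | None = None) -> str:
    n = syllables or rng.randint(2, 4)
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n)
    )


def _is_nounlike(term: str, language: str) -> bool:
    """All tokens tagged NOUN with identity lemmas — the generated term
    behaves as a plain noun phrase under the pipeline's tagger, so plants
    test the matcher rather than tagger suffix heuristics."""
    from .textproc import get_tagger

    records = get_tagger().tag(term, language)
    return bool(records) and all(
        r.pos == "NOUN" and r.lemma == r.surface.lower() for r in records
    )


def _term(rng: random.Random, language: str, multiword_prob: float = 0.3) -> str:
    while True:
        if rng.random() < multiword_prob:
            cand = " ".join(_word(rng) for _ in range(rng.randint(2, 3)))
        else:
            cand = _word(rng, syllables=rng.randint(3, 5))
        if _is_nounlike(cand, language):
            return cand


# ---------------------------------------------------------------------------
# ontology generator
# ---------------------------------------------------------------------------


@dataclass
class OntologyManifest:
    seed: int
    #: concept_id -> {language: term}
    terms: dict[str, dict[str, str]] = field(default_factory=dict)
    table_path: str = ""

    def rows(self) -> list[tuple[str, str, str]]:
        return [
            (cid, term, lang)
            for cid, by_lang in sorted(self.terms.items())
            for lang, term in sorted(by_lang.items())
        ]


def generate_ontology(
    n_concepts: int,
    languages: list[str],
    seed: int,
    out_dir: str | Path,
    filename: str = "concepts.tsv",
) -> OntologyManifest:
    """Write a TSV concept table of ``n_concepts`` per-language term
    variants; ~30% multiword terms; no duplicate triples."""
    if n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = OntologyManifest(seed=seed)
    used: set[tuple[str, str]] = set()
    for i in range(n_concepts):
        cid = f"C{i:04d}"
        by_lang: dict[str, str] = {}
        for lang in languages:
            term = _term(rng, lang)
            while (lang, term) in used:
                term = _term(rng, lang)
            used.add((lang, term))
            by_lang[lang] = term
        manifest.terms[cid] = by_lang
    path = out_dir / filename
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_id\tterm\tlanguage\n")
        for cid, term, lang in manifest.rows():
            fh.write(f"{cid}\t{term}\t{lang}\n")
    manifest.table_path = str(path)
    return manifest


# ---------------------------------------------------------------------------
# corpus generator with planted concept mentions
# ---------------------------------------------------------------------------


@dataclass
class Plant:
    concept_id: str
    source_term: str      # vocabulary surface form
    surface: str          # form actually embedded (may carry one edit)
    mutated: bool


@dataclass
class CorpusManifest:
    seed: int
    language: str = "en"
    #: doc filename -> list of plants
    plants: dict[str, list[Plant]] = field(default_factory=dict)
    doc_paths: dict[str, str] = field(default_factory=dict)

    def planted_concepts(self, doc: str) -> set[str]:
        return {p.concept_id for p in self.plants[doc]}


def _mutate(rng: random.Random, term: str, language: str) -> str:
    """One random character edit (substitute/delete/insert), never touching
    spaces, producing a noun-like string at edit distance exactly 1."""
    letters = [i for i, ch in enumerate(term) if ch != " "]
    while True:
        op = rng.choice(("sub", "del", "ins"))
        i = rng.choice(letters)
        if op == "sub":
            repl = rng.choice([c for c in _CONSONANTS + _VOWELS if c != term[i]])
            out = term[:i] + repl + term[i + 1 :]
        elif op == "del":
            out = term[:i] + term[i + 1 :]
        else:
            out = term[:i] + rng.choice(_CONSONANTS + _VOWELS) + term[i:]
        if (
            out != term
            and "  " not in out
            and not out.startswith(" ")
            and not out.endswith(" ")
            and _is_nounlike(out, language)
        ):
            return out


def generate_corpus(
    n_docs: int,
    ontology_manifest: OntologyManifest,
    mutation_rate: float,
    seed: int,
    out_dir: str | Path,
    language: str = "en",
) -> CorpusManifest:
    """Write ``n_docs`` HTML files, each embedding 1-5 planted vocabulary
    terms inside filler sentences.  With probability ``mutation_rate`` a
    plant (term length >= 6 only) receives one character edit.  The manifest
    records every plant."""
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = CorpusManifest(seed=seed, language=language)
    concept_ids = [
        cid for cid, by_lang in sorted(ontology_manifest.terms.items()) if language in by_lang
    ]
    filler = _FILLER_BY_LANG.get(language, _FILLER_BY_LANG["en"])
    for d in range(n_docs):
        name = f"doc{d:03d}.html"
        n_plants = rng.randint(1, 5)
        chosen = rng.sample(concept_ids, min(n_plants, len(concept_ids)))
        plants: list[Plant] = []
        sentences: list[str] = []
        for cid in chosen:
            term = ontology_manifest.terms[cid][language]
            mutated = False
            surface = term
            if len(term) >= 6 and rng.random() < mutation_rate:
                surface = _mutate(rng, term, language)
                mutated = True
            plants.append(Plant(concept_id=cid, source_term=term, surface=surface, mutated=mutated))
            pre = " ".join(rng.choice(filler) for _ in range(rng.randint(2, 5)))
            post = " ".join(rng.choice(filler) for _ in range(rng.randint(2, 5)))
            sentences.append(f"{pre} {surface} {post}.")
        html = (
            "<html><head><title>"
            + f"generated document {d}"
            + "</title></head><body>"
            + "".join(f"<p>{s}</p>" for s in sentences)
            + "</body></html>"
        )
        path = out_dir / name
        path.write_text(html, encoding="utf-8")
        manifest.plants[name] = plants
        manifest.doc_paths[name] = str(path)
    return manifest


# ---------------------------------------------------------------------------
# linkable website generator
# ---------------------------------------------------------------------------


@dataclass
class SiteManifest:
    seed: int
    host: str
    root_dir: str
    #: page filename -> outgoing links as (url, on_domain)
    link_graph: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)

    def on_domain_pages(self) -> list[str]:
        return sorted(self.link_graph)

    def bfs_order(self, start: str = "index.html") -> list[str]:
        """Independent BFS over the manifest graph (page filenames)."""
        from collections import deque

        order, seen, q = [], {start}, deque([start])
        while q:
            page = q.popleft()
            order.append(page)
            for url, on_domain in self.link_graph.get(page, []):
                if not on_domain:
                    continue
                target = url.rsplit("/", 1)[-1]
                if target not in seen:
                    seen.add(target)
                    q.append(target)
        return order


def generate_site(
    n_pages: int,
    n_offdomain_links: int,
    seed: int,
    out_dir: str | Path,
    host: str = "example.org",
) -> SiteManifest:
    """Write a connected on-domain site of ``n_pages`` HTML pages rooted at
    ``index.html``, with ``n_offdomain_links`` external links sprinkled in.
    The manifest records the full link graph with on/off-domain labels."""
    if n_pages < 1:
        raise ValueError("n_pages must be >= 1")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ["index.html"] + [f"page{i:03d}.html" for i in range(1, n_pages)]
    manifest = SiteManifest(seed=seed, host=host, root_dir=str(out_dir))
    links: dict[str, list[tuple[str, bool]]] = {n: [] for n in names}
    # spanning links guarantee connectivity from the root
    for i in range(1, n_pages):
        parent = names[rng.randrange(0, i)]
        links[parent].append((f"http://{host}/{names[i]}", True))
    # extra on-domain edges (including occasional cycles)
    for _ in range(n_pages // 2):
        a, b = rng.choice(names), rng.choice(names)
        edge = (f"http://{host}/{b}", True)
        if a != b and edge not in links[a]:
            links[a].append(edge)
    # off-domain links
    for k in range(n_offdomain_links):
        page = rng.choice(names)
        links[page].append((f"http://offsite{k:02d}.example.com/x", False))
    for name in names:
        body = "".join(
            f'<p><a href="{url}">link</a></p>' for url, _ in links[name]
        )
        (out_dir / name).write_text(
            f"<html><head><title>{name}</title></head><body>"
            f"<p>content of {name}</p>{body}</body></html>",
            encoding="utf-8",
        )
    manifest.link_graph = links
    return manifest


# ---------------------------------------------------------------------------
# user session simulator
# ---------------------------------------------------------------------------


@dataclass
class SessionLog:
    seed: int
    #: emitted events as dicts (the replayable oracle)
    emissions: list[dict] = field(default_factory=list)

    def click_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for e in self.emissions:
            if e["kind"] == "click":
                key = (e["user_id"], e["doc_id"])
                counts[key] = counts.get(key, 0) + 1
        return counts

    def last_ratings(self) -> dict[tuple[str, str], int]:
        ratings: dict[tuple[str, str], int] = {}
        for e in self.emissions:
            if e["kind"] == "rating":
                ratings[(e["user_id"], e["doc_id"])] = e["rating_value"]
        return ratings

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.emissions, indent=1), encoding="utf-8")


def simulate_user(
    user_id: str,
    doc_ids: list[str],
    n_events: int,
    seed: int,
    click_prob: float = 0.7,
) -> tuple[list, SessionLog]:
    """Emit ``n_events`` clicks/ratings from one user over the given
    documents.  Returns the events plus an emission log that serves as the
    oracle for preference-store counts."""
    from .profiles import PreferenceEvent

    rng = random.Random(seed)
    log = SessionLog(seed=seed)
    events = []
    for t in range(n_events):
        doc = rng.choice(doc_ids)
        if rng.random() < click_prob:
            rec = {"user_id": user_id, "doc_id": doc, "kind": "click",
                   "rating_value": None, "timestamp": float(t)}
        else:
            rec = {"user_id": user_id, "doc_id": doc, "kind": "rating",
                   "rating_value": rng.randint(1, 5), "timestamp": float(t)}
        log.emissions.append(rec)
        events.append(PreferenceEvent(**rec))
    return events, log
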