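# phir — personal health information recommender

Patients searching the open web for information about their disease face
both information overload and highly variable quality. `phir` implements
the alternative: a closed, expert-curated repository. Clinicians register
trusted web resources; the system crawls each registered site (same domain
only), extracts the visible text, and annotates every page with concepts
from a clinical vocabulary by approximate string matching on noun lemmas.
Patients search this repository through a BM25 engine whose results are
personalized twice — first merged with documents relevant to the
medical conditions logged in their health record, then re-ranked by their
own clicks and 1–5 star ratings.

It is aimed at builders of patient-facing health-record portals and at
researchers studying profile-aware medical information retrieval. English,
German, and Italian are supported.

## The model

**Annotation.** Text is tagged and lemmatized (a deterministic rule-based
tagger ships by default; backends are pluggable). Noun lemmas and 2–3-token
windows containing a noun are matched against vocabulary terms with
normalized Levenshtein similarity, sim(a,b) = 1 − lev(a,b)/max(|a|,|b|),
accepted at a threshold τ (default 0.85).

**Retrieval.** A four-field inverted index (title, content, tags, concept
ids) scored with field-weighted BM25,

    score(q,d) = Σ_f w_f Σ_{t∈q} idf(t,f) · tf·(k1+1)/(tf + k1·(1−b+b·dl/avgdl)),
    idf = ln(1 + (N − df + 0.5)/(df + 0.5)),   k1 = 1.2, b = 0.75,

with weights title 2.0, tags 1.5, concepts 1.5, content 1.0.

**Personalization.** For user u with query q, the engine computes the query
result set Q and a profile result set P (one search per profile concept;
max score per document) and presents three tiers: documents in **both** P
and Q (scores summed), then remaining **profile** documents, then remaining
**query** documents. Recorded feedback re-sorts within tiers only:
score × (1 + 0.1·(rating − 3)) × (1 + 0.05·min(clicks, 4)). Anonymous or
unprofiled users get exactly the plain search ranking.

Vocabulary input is a plain TSV (`concept_id`, `term`, `language`) — a
stand-in for licensed terminologies such as SNOMED CT, whose release files
cannot be bundled; an OBO reader is included.

## Worked example

```python
from phir import *

ontology = build_index([
    Concept("254837009", "breast cancer", "en"),
    Concept("363346000", "cancer", "en"),
    Concept("367336001", "chemotherapy", "en"),
    Concept("195967001", "asthma", "en"),
])

# ... register documents d1/d3/d5/d6, annotate, and index them ...

profiles = ProfileStore()
alice = profiles.get_or_create("alice")
add_condition(alice, {"diagnosis": "breast cancer", "tumor_size_mm": "14"}, ontology)
print("profile concepts:", alice.concept_ids())

rec = Recommender(index, profiles, PreferenceStore())
for r in rec.recommend("alice", "surgery recovery"):
    print(f"rank {r.final_rank}  tier {int(r.tier)}  score {r.boosted_score:.4f}  {r.doc_id}")
```

prints

```
profile concepts: ['254837009', '363346000']
rank 1  tier 2  score 1.6655  d1
rank 2  tier 2  score 1.3636  d3
rank 3  tier 3  score 2.8353  d6
```

The profile's "breast cancer" diagnosis matched two concepts (the numeric
`tumor_size_mm` field is never annotated). Documents d1 and d3 carry those
concepts, so they outrank d6 — the only document actually matching the
query "surgery recovery" — despite d6's higher raw BM25 score: tier
membership dominates, score orders within a tier. After
`rec.prefs.record_event(make_event("alice", "d3", "rating", rating_value=5))`
the same query prints d3 at score 1.6364 (= 1.3636 × 1.2), still rank 2 in
tier 2: feedback boosts never move a document across tiers.

The same flow is available from the shell (`phir register`, `phir search`,
`phir recommend`, `phir rate`, `phir click`, `phir serve`,
`phir fixtures ...`) and over JSON HTTP (`GET /search`, `POST /feedback`,
`POST /register`, `GET /health`).

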