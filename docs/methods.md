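# Methods

## Overview

`phir` implements a curated health-information search and recommendation
pipeline with two faces. Experts register trusted web resources through a
small form (URL, title, text/video type, language, optional tags); the
system crawls the resource's site, extracts visible text, and attaches
clinical-vocabulary concepts to every page by approximate string matching.
Patients then query a BM25 search engine whose results are merged with
results derived from their annotated medical profile and re-ranked using
their recorded clicks and ratings.

This note documents the model behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## Concept vocabulary

Clinical vocabularies (SNOMED CT, LOINC, RXTerms) are license-restricted,
so the store reads a plain three-column TSV (`concept_id`, `term`,
`language`) in which every row is an independently matchable term — a
concept may appear on many rows (synonyms, translations). Supported
languages are English, German, and Italian. An optional OBO reader maps
`[Term]` stanzas (`id`, `name`, `synonym`) onto the same row model via
`obonet`.

Term normalization is Unicode case-folding plus collapse of internal
whitespace. Diacritics are **not** stripped: they are phonemic in German
and Italian, and stripping them would merge distinct terms. Exact duplicate
(id, term, language) triples are dropped; the same term under different ids
is kept, and lookups return all ids (ambiguity is resolved downstream by
keeping every match).

No hierarchy or subsumption semantics are modelled; matching is purely
lexical.

## Text processing

HTML is parsed with `lxml`; `script`, `style`, `noscript`, `nav`,
`header`, `footer`, and `aside` subtrees are dropped and the remaining
text is concatenated in reading order.

Tagging/lemmatization is pluggable behind a one-method interface. The
shipped backend is a deterministic rule-based tagger for en/de/it: small
closed-class stopword lists mark function words, suffix heuristics split
off verbs and adjectives, and plural endings are stripped to approximate
the dictionary form (en `-s/-es/-ies`; de `-en/-er/-e/-n/-s` with a
minimum stem of four characters; it `-i → -o` with `-e` left in place
because the singular is not recoverable). The choice of a rule backend
over a statistical model is deliberate: it is versionless and has no
download, so every downstream artifact (annotations, index contents,
ranks) is bit-reproducible. Its POS accuracy on real prose is of course
far below a statistical tagger's; a model-based backend can be registered
under a name without touching callers. Languages outside the supported set
degrade to whitespace tokenization where every alphabetic token of length
≥ 3 counts as a candidate noun, logged as degraded mode.

Only noun lemmas feed concept matching. Because many vocabulary terms are
multiword, candidate strings also include sliding windows of 2–3
consecutive token lemmas containing at least one noun; without the
windows, terms like "breast cancer" would be unreachable from single-noun
candidates.

## Similarity matching

The matcher scores a candidate against a vocabulary term with normalized
Levenshtein similarity on normalized strings:

    sim(a, b) = 1 − lev(a, b) / max(|a|, |b|)

which is 1.0 exactly on normalized equality and symmetric. The default
acceptance threshold is τ = 0.85, configurable per run; at that level a
single edit is tolerated from length 7 upward, and τ = 0.8 from length 5.
The implementation is a banded dynamic program: the threshold implies a
maximum admissible distance `⌊(1 − τ)·maxlen⌋`, pairs whose length
difference exceeds it are skipped outright, and the DP aborts as soon as
the minimum of the current band exceeds the bound. This makes matching a
document against thousands of terms linear in practice rather than
quadratic.

Per (candidate, concept) only the best-similarity term is kept; per
document, annotations are deduplicated on (concept, origin) and capped at
the 50 highest-similarity entries to bound index size. Annotations record
their origin: `content` (from extracted text) or `tag` (from the expert's
tags). Video resources get tag-origin annotations only — transcript
processing is out of scope.

## Crawling

Registration of a text resource triggers a breadth-first crawl from the
seed URL, bounded by `max_pages` (default 500), `max_depth` (default 5),
and a politeness delay (default 1 s over HTTP; tests and fixtures use an
injected local-directory fetcher with no delay). The same-domain rule is
host equality after lowercasing and `www.` stripping; off-domain links are
recorded on the page but never fetched. URLs are canonicalized (fragment
dropped, default ports removed, relative links resolved, `mailto:` and
`javascript:` discarded) and never fetched twice. `robots.txt` is honoured
for HTTP transport. Crawled child pages inherit the parent form entry's
title, language, type and tags, and each becomes its own registered
document keyed by a hash of its canonical URL, so re-registration replaces
rather than duplicates.

## Indexing and retrieval

The index is an in-memory inverted index over four fields — `title`,
`content`, `tags`, `concepts` — with JSON persistence. Text fields are
analyzed with the same lemmatizer as annotation (all parts of speech, not
only nouns, since query words need not be nouns); concept ids are indexed
verbatim. Scoring is field-weighted BM25:

    score(q, d) = Σ_f w_f Σ_{t∈q} idf(t,f) · tf·(k1+1) / (tf + k1·(1 − b + b·dl_f/avgdl_f))
    idf(t, f)  = ln(1 + (N − df + 0.5)/(df + 0.5))

with k1 = 1.2, b = 0.75, and weights title 2.0, tags 1.5, concepts 1.5,
content 1.0 (all configurable). Ties are broken by doc id so rankings are
deterministic; only positive-score documents are returned. On corpora of
≤ 20 documents the engine is verified against exhaustive per-document
evaluation of the formula to 1e−9.

## Profiles and the numeric-field rule

Patients log conditions as free-form named fields. Textual values pass
through the same candidate-extraction and similarity matcher as documents;
values that fully parse as numbers after stripping one of a small unit
suffix list (mm, cm, kg, mg, g, ml, %) are never annotated — measurements
carry no matchable terminology, only noise (a size "14" must not match a
code "14"). Decimal commas are accepted alongside decimal points for the
de/it locales.

## Recommendation

Given a query from user `u`:

1. **Query set Q** — plain BM25 search.
2. **Profile set P** — one search per distinct concept in the profile's
   condition annotations, querying the `concepts` field by id and the text
   fields by the matched term's lemmas; per document the max score over
   those searches.
3. **Three-tier merge** — tier 1: documents in P ∩ Q with the two scores
   summed; tier 2: P \ Q; tier 3: Q \ P. Tiers are concatenated, each
   sorted by score descending. The first tier is implemented as the
   intersection: only then are the later "remaining" tiers non-empty, and
   the tier structure matches the Venn-style combination of the two result
   sets that motivates the hierarchy.
4. **Feedback boost** — multiplicative, bounded, within-tier only:
   `score × (1 + 0.1·(r − 3))` when a rating r exists and
   `× (1 + 0.05·min(clicks, 4))`. A 3-star rating and zero clicks are
   exactly neutral; the worst case (1 star) scales by 0.8 and the best
   (5 stars, ≥ 4 clicks) by 1.44, so scores stay positive and a document
   can never leave its tier. The latest rating per (user, document)
   supersedes earlier ones; clicks accumulate. Clicked ("already seen")
   content is promoted, on the assumption that clicks signal interest;
   demotion of seen content would be the one-line opposite choice.

An unknown or empty profile makes P empty, and the output degrades exactly
to the unpersonalized search ranking — anonymous search is supported.

## Service and CLI

A WSGI app (stdlib, no framework) exposes `GET /search`, `POST /feedback`,
`POST /register`, `GET /health`, returning canonical JSON (sorted keys, no
insignificant whitespace). The result-document schema is published in
`src/phir/schemas/result_document.schema.json` and enforced by pydantic
models. The text/video type filter mirrors the client app's tabs and is
applied after ranking without re-ranking. The `phir` CLI wraps the same
library calls over a file-based workspace (TSV vocabulary, JSON-lines
document store, JSON index, JSON profiles, JSON-lines preference log).

## Synthetic data

The `fixtures` module generates everything the tests need, deterministically
from a seed, as plain files read back through the normal code paths:

- **Ontologies** — pronounceable consonant-vowel nonsense terms, ~30%
  multiword, per-language variants, no duplicate triples.
- **Corpora** — HTML documents embedding 1–5 planted terms in filler
  sentences; with a configurable probability a plant (terms ≥ 6 characters
  only) receives exactly one character edit. Generated and mutated terms
  are constrained to behave as plain noun phrases under the shipped tagger
  (all tokens tagged NOUN with identity lemmas), so recall measurements
  exercise the similarity matcher rather than the tagger's suffix
  heuristics.
- **Sites** — a connected on-domain link graph rooted at an index page with
  off-domain links sprinkled in; the manifest records the full labelled
  graph.
- **Sessions** — click/rating streams with an emission log.

Each generator returns a manifest that fully determines its output; tests
consult only manifests, never generator internals. The generators emulate
*structure* (which terms occur where, which links exist, which events
happened) and none of the properties of real clinical text — no grammar,
no negation, no coreference, no boilerplate-heavy page layouts. Passing
recall/precision/closure checks therefore demonstrates the correctness of
the matching, crawling, and ranking machinery, not NLP quality on real
medical prose.

## Problem sizes and verification

The shipped verification uses 50 random corpora of ≤ 20 documents over a
30-term vocabulary for BM25 oracle equivalence, 1,000 random string pairs
for the similarity metric, a 50-document corpus over 60 concepts for
annotator recall/precision, a 50-page site with 10 off-domain links for
crawl closure, 200 random scored-set pairs for the tier partition, and 500
random feedback cases. `scripts/acceptance.py` re-runs all of these from a
given seed and reports the measured quantities.

## Known limitations

- The rule tagger's POS and lemma decisions are heuristic; real-text recall
  will be lower than on generated corpora.
- Cross-language search is not supported: a query is evaluated in one
  language, and concept ids only bridge languages when documents were
  annotated in the query language.
- Similarity is character-level; token reorderings ("cancer of the breast"
  vs "breast cancer") do not match.
- The crawler renders no JavaScript and reads no sitemaps.
- Boost coefficients are design constants, not learned from feedback.
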