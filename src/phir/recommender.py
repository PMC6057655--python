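"""Personalized ranking: profile result set, three-tier merge, feedback boost.

The recommender combines two result sets — documents relevant to the
patient's annotated medical conditions, and documents relevant to the typed
query — into a fixed hierarchy:

  tier 1  documents relevant to BOTH profile and query (scores summed),
  tier 2  remaining profile-relevant documents,
  tier 3  remaining query-relevant documents,

each tier internally sorted by score descending.  Recorded feedback then
re-sorts within tiers only: a 1-5 star rating multiplies the score by
``1 + 0.1 * (rating - 3)`` and clicks by ``1 + 0.05 * min(clicks, 4)``, so
boosts are bounded, scores stay positive, and a document can never change
tier.  An unknown or empty profile degrades exactly to plain search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

from .config import DEFAULT_CONFIG, PhirConfig, logger
from .profiles import PatientProfile, PreferenceStore, ProfileStore
from .search_index import ScoredHit, SearchIndex


class Tier(IntEnum):
    BOTH = 1
    PROFILE_ONLY = 2
    QUERY_ONLY = 3


@dataclass(frozen=True)
class TieredResult:
    hit: ScoredHit
    tier: Tier
    boosted_score: float
    final_rank: int = 0

    @property
    def doc_id(self) -> str:
        return self.hit.doc_id


def profile_result_set(profile: PatientProfile | None, index: SearchIndex) -> list[ScoredHit]:
    """Documents relevant to the profile's condition concepts.

    One search per distinct concept: the concepts field is queried by
    concept_id and the text fields by the matched vocabulary term; a
    document's profile score is the max over those searches.  Empty or
    missing profile yields the empty set.
    """
    if profile is None or not profile.conditions:
        return []
    by_concept: dict[str, set[str]] = {}
    for ann in profile.concept_annotations():
        by_concept.setdefault(ann.concept_id, set()).add(ann.matched_term)

    best: dict[str, ScoredHit] = {}
    for concept_id in sorted(by_concept):
        terms = [concept_id]
        for matched_term in sorted(by_concept[concept_id]):
            terms.extend(index.analyze_query(matched_term, profile.language))
        for hit in index.search_terms(terms):
            prior = best.get(hit.doc_id)
            if prior is None or hit.score > prior.score:
                best[hit.doc_id] = hit
    hits = list(best.values())
    hits.sort(key=lambda h: (-h.score, h.doc_id))
    return hits


def three_tier_merge(
    profile_hits: list[ScoredHit], query_hits: list[ScoredHit]
) -> list[TieredResult]:
    """Partition P ∪ Q into the three tiers and concatenate them.

    Documents in both sets get tier 1 with the two scores summed; the rest
    of P gets tier 2 and the rest of Q tier 3.  Each document appears in
    exactly one tier; tiers are internally sorted by score descending with
    doc_id tie-breaks.
    """
    p = {h.doc_id: h for h in profile_hits}
    q = {h.doc_id: h for h in query_hits}
    results: list[TieredResult] = []
    for doc_id in p.keys() & q.keys():
        merged = ScoredHit(
            doc_id=doc_id,
            score=p[doc_id].score + q[doc_id].score,
            matched_fields=p[doc_id].matched_fields | q[doc_id].matched_fields,
        )
        results.append(TieredResult(hit=merged, tier=Tier.BOTH, boosted_score=merged.score))
    for doc_id in p.keys() - q.keys():
        results.append(TieredResult(hit=p[doc_id], tier=Tier.PROFILE_ONLY, boosted_score=p[doc_id].score))
    for doc_id in q.keys() - p.keys():
        results.append(TieredResult(hit=q[doc_id], tier=Tier.QUERY_ONLY, boosted_score=q[doc_id].score))
    results.sort(key=lambda r: (r.tier, -r.hit.score, r.doc_id))
    return results


def boost_factor(
    rating: int | None,
    clicks: int,
    config: PhirConfig = DEFAULT_CONFIG,
) -> float:
    """Multiplicative feedback boost; 1.0 with no events or a neutral
    3-star rating and zero clicks."""
    factor = 1.0
    if rating is not None:
        factor *= 1.0 + config.rating_coefficient * (rating - 3)
    if clicks > 0:
        factor *= 1.0 + config.click_coefficient * min(clicks, config.click_cap)
    return factor


def apply_preference_boost(
    results: list[TieredResult],
    prefs: PreferenceStore,
    user_id: str | None,
    config: PhirConfig = DEFAULT_CONFIG,
) -> list[TieredResult]:
    """Re-score with recorded feedback and re-sort WITHIN each tier; the
    tier assignment itself never changes."""
    if user_id is None:
        return list(results)
    boosted = [
        replace(
            r,
            boosted_score=r.hit.score
            * boost_factor(
                prefs.rating(user_id, r.doc_id),
                prefs.click_count(user_id, r.doc_id),
                config=config,
            ),
        )
        for r in results
    ]
    boosted.sort(key=lambda r: (r.tier, -r.boosted_score, r.doc_id))
    return boosted


def _assign_ranks(results: list[TieredResult]) -> list[TieredResult]:
    return [replace(r, final_rank=i) for i, r in enumerate(results, start=1)]


class Recommender:
    """Facade tying together the index, profile store, and preference store."""

    def __init__(
        self,
        index: SearchIndex,
        profiles: ProfileStore | None = None,
        prefs: PreferenceStore | None = None,
        config: PhirConfig = DEFAULT_CONFIG,
    ):
        self.index = index
        self.profiles = profiles or ProfileStore()
        self.prefs = prefs or PreferenceStore()
        self.config = config

    def recommend(
        self,
        user_id: str | None,
        query: str,
        language: str | None = None,
        top_k: int = 20,
    ) -> list[TieredResult]:
        """Personalized ranked list for a user and query.

        Unknown users are treated as empty profiles (anonymous search is
        supported), in which case the output equals plain search ordering.
        """
        profile = self.profiles.get(user_id) if user_id is not None else None
        if user_id is not None and profile is None:
            logger.warning("unknown user %r; anonymous search", user_id)
        lang = language or (profile.language if profile else "en")
        query_hits = self.index.search(query, language=lang, top_k=None)
        profile_hits = profile_result_set(profile, self.index)
        merged = three_tier_merge(profile_hits, query_hits)
        boosted = apply_preference_boost(merged, self.prefs, user_id, config=self.config)
        return _assign_ranks(boosted[:top_k])


def recommend(
    user_id: str | None,
    query: str,
    index: SearchIndex,
    profiles: ProfileStore | None = None,
    prefs: PreferenceStore | None = None,
    top_k: int = 20,
    config: PhirConfig = DEFAULT_CONFIG,
) -> list[TieredResult]:
    return Recommender(index, profiles, prefs, config).recommend(
        user_id, query, top_k=top_k
    )
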