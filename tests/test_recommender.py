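"""Tiered merge, profile result set, and preference boosting."""

import random

import pytest

from phir import (
    PatientProfile,
    PreferenceEvent,
    PreferenceStore,
    ProfileStore,
    Recommender,
    ScoredHit,
    Tier,
    add_condition,
    apply_preference_boost,
    boost_factor,
    profile_result_set,
    three_tier_merge,
)


def hits_from(d: dict[str, float]) -> list[ScoredHit]:
    return [ScoredHit(doc_id=k, score=v) for k, v in d.items()]


def oracle_merge(p: dict[str, float], q: dict[str, float]):
    """Brute-force re-statement of the tier definitions from plain set
    algebra: intersection first (scores summed), then profile-only, then
    query-only, each tier sorted by score descending with id tie-breaks."""
    both = sorted(((k, p[k] + q[k]) for k in set(p) & set(q)), key=lambda kv: (-kv[1], kv[0]))
    ponly = sorted(((k, p[k]) for k in set(p) - set(q)), key=lambda kv: (-kv[1], kv[0]))
    qonly = sorted(((k, q[k]) for k in set(q) - set(p)), key=lambda kv: (-kv[1], kv[0]))
    return both, ponly, qonly


class TestThreeTierMerge:
    def test_worked_example(self):
        out = three_tier_merge(
            hits_from({"d1": 0.9, "d2": 0.5}), hits_from({"d2": 0.8, "d3": 0.7})
        )
        assert [(r.doc_id, r.tier) for r in out] == [
            ("d2", Tier.BOTH),
            ("d1", Tier.PROFILE_ONLY),
            ("d3", Tier.QUERY_ONLY),
        ]
        assert out[0].hit.score == pytest.approx(1.3)  # scores summed in tier 1

    def test_empty_profile_preserves_query_ordering(self):
        q = hits_from({"a": 0.2, "b": 0.9, "c": 0.5})
        out = three_tier_merge([], q)
        assert [r.doc_id for r in out] == ["b", "c", "a"]
        assert all(r.tier == Tier.QUERY_ONLY for r in out)

    def test_disjoint_sets_have_empty_tier_one(self):
        rng = random.Random(1)
        p = {f"p{i}": rng.random() for i in range(10)}
        q = {f"q{i}": rng.random() for i in range(7)}
        out = three_tier_merge(hits_from(p), hits_from(q))
        assert len(out) == 17
        assert all(r.tier != Tier.BOTH for r in out)

    def test_random_instances_match_set_algebra_oracle(self):
        """Partition property on random instances: tiers disjoint, union
        covers P ∪ Q, ordering equals the brute-force oracle."""
        rng = random.Random(42)
        for _ in range(100):
            ids = [f"d{i}" for i in range(rng.randint(0, 12))]
            p = {d: round(rng.random(), 6) for d in ids if rng.random() < 0.5}
            q = {d: round(rng.random(), 6) for d in ids if rng.random() < 0.5}
            out = three_tier_merge(hits_from(p), hits_from(q))
            both, ponly, qonly = oracle_merge(p, q)
            assert [r.doc_id for r in out] == [k for k, _ in both + ponly + qonly]
            assert len({r.doc_id for r in out}) == len(out)  # exactly once
            assert {r.doc_id for r in out} == set(p) | set(q)


class TestProfileResultSet:
    def test_empty_profile_empty_set(self, indexed_corpus):
        index, _, _ = indexed_corpus
        assert profile_result_set(None, index) == []
        assert profile_result_set(PatientProfile("u1"), index) == []

    def test_concept_annotated_docs_returned(self, indexed_corpus, small_ontology):
        index, _, _ = indexed_corpus
        profile = PatientProfile("u1")
        add_condition(profile, {"diagnosis": "breast cancer"}, small_ontology)
        hits = profile_result_set(profile, index)
        # d1 and d3 carry concept C1 in the corpus fixture
        assert {h.doc_id for h in hits} >= {"d1", "d3"}

    def test_duplicate_concepts_collapse_by_max(self, indexed_corpus, small_ontology):
        index, _, _ = indexed_corpus
        one = PatientProfile("u1")
        add_condition(one, {"diagnosis": "breast cancer"}, small_ontology)
        two = PatientProfile("u2")
        add_condition(two, {"diagnosis": "breast cancer"}, small_ontology)
        add_condition(two, {"history": "breast cancer"}, small_ontology)
        assert [
            (h.doc_id, pytest.approx(h.score)) for h in profile_result_set(two, index)
        ] == [(h.doc_id, h.score) for h in profile_result_set(one, index)]


class TestPreferenceBoost:
    def test_neutral_inputs_leave_scores_unchanged(self):
        results = three_tier_merge(hits_from({"d1": 0.5}), hits_from({"d2": 0.4}))
        prefs = PreferenceStore()
        assert apply_preference_boost(results, prefs, "u") == results
        # rating 3 with zero clicks is exactly neutral
        prefs.record_event(PreferenceEvent("u", "d1", "rating", rating_value=3))
        out = apply_preference_boost(results, prefs, "u")
        assert [r.boosted_score for r in out] == [r.boosted_score for r in results]

    def test_rating_five_beats_rating_one_at_equal_base(self):
        results = three_tier_merge([], hits_from({"a": 0.6, "b": 0.6}))
        prefs = PreferenceStore()
        prefs.record_event(PreferenceEvent("u", "b", "rating", rating_value=5))
        prefs.record_event(PreferenceEvent("u", "a", "rating", rating_value=1))
        out = apply_preference_boost(results, prefs, "u")
        assert [r.doc_id for r in out] == ["b", "a"]
        assert out[0].boosted_score == pytest.approx(0.6 * 1.2)
        assert out[1].boosted_score == pytest.approx(0.6 * 0.8)

    def test_click_boost_saturates(self):
        assert boost_factor(None, 0) == 1.0
        assert boost_factor(None, 1) == pytest.approx(1.05)
        assert boost_factor(None, 4) == pytest.approx(1.20)
        assert boost_factor(None, 400) == pytest.approx(1.20)  # capped

    def test_boost_never_crosses_tiers(self):
        """Randomized: heavy feedback reorders within tiers only."""
        rng = random.Random(7)
        for _ in range(50):
            p = {f"d{i}": rng.uniform(0.1, 1.0) for i in range(rng.randint(1, 8))}
            q = {f"d{i}": rng.uniform(0.1, 1.0) for i in range(rng.randint(1, 8)) if rng.random() < 0.6}
            results = three_tier_merge(hits_from(p), hits_from(q))
            prefs = PreferenceStore()
            for r in results:
                if rng.random() < 0.7:
                    prefs.record_event(
                        PreferenceEvent("u", r.doc_id, "rating", rating_value=rng.randint(1, 5))
                    )
                for _ in range(rng.randint(0, 6)):
                    prefs.record_event(PreferenceEvent("u", r.doc_id, "click"))
            out = apply_preference_boost(results, prefs, "u")
            assert {r.doc_id: r.tier for r in out} == {r.doc_id: r.tier for r in results}
            tiers = [r.tier for r in out]
            assert tiers == sorted(tiers)  # tier blocks stay contiguous and ordered


class TestRecommend:
    def _recommender(self, indexed_corpus, small_ontology):
        index, _, _ = indexed_corpus
        profiles = ProfileStore()
        profile = profiles.get_or_create("patient", language="en")
        add_condition(profile, {"diagnosis": "breast cancer"}, small_ontology)
        return Recommender(index, profiles, PreferenceStore())

    def test_unknown_user_equals_plain_search(self, indexed_corpus, small_ontology):
        rec = self._recommender(indexed_corpus, small_ontology)
        index, _, _ = indexed_corpus
        out = rec.recommend("stranger", "asthma management")
        plain = index.search("asthma management")
        assert [r.doc_id for r in out] == [h.doc_id for h in plain]
        assert [r.boosted_score for r in out] == [pytest.approx(h.score) for h in plain]

    def test_profile_docs_precede_disjoint_query_docs(self, indexed_corpus, small_ontology):
        rec = self._recommender(indexed_corpus, small_ontology)
        out = rec.recommend("patient", "surgery recovery")
        tiers = {r.doc_id: r.tier for r in out}
        assert tiers["d6"] == Tier.QUERY_ONLY  # query hit, no profile concept
        profile_docs = [d for d, t in tiers.items() if t == Tier.PROFILE_ONLY]
        assert set(profile_docs) >= {"d1", "d3"}
        assert max(out[i].final_rank for i, r in enumerate(out) if out[i].doc_id in profile_docs) < [
            r.final_rank for r in out if r.doc_id == "d6"
        ][0]

    def test_top_k_truncation_and_rank_assignment(self, indexed_corpus, small_ontology):
        rec = self._recommender(indexed_corpus, small_ontology)
        out = rec.recommend("patient", "cancer", top_k=1)
        assert len(out) == 1
        assert out[0].final_rank == 1
        full = rec.recommend("patient", "cancer", top_k=10)
        assert [r.final_rank for r in full] == list(range(1, len(full) + 1))
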