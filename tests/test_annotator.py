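"""String similarity, concept matching, and the registration pipeline."""

import random
import string

import edlib
import pytest
from hypothesis import given, settings, strategies as st

from phir import (
    DocumentStore,
    PhirConfig,
    LocalDirectoryFetcher,
    RegistrationEntry,
    RegistrationError,
    annotate_document,
    build_index,
    candidate_strings,
    extract_text,
    levenshtein,
    match_concepts,
    register,
    string_similarity,
)
from phir.ontology import Concept
from phir.fixtures import generate_corpus, generate_ontology, generate_site
from phir.textproc import get_tagger


def oracle_similarity(a: str, b: str) -> float:
    """Independent oracle: edlib edit distance over normalized strings."""
    from phir.ontology import normalize_term

    na, nb = normalize_term(a), normalize_term(b)
    d = edlib.align(na, nb)["editDistance"]
    return 1.0 - d / max(len(na), len(nb))


class TestStringSimilarity:
    def test_identity(self):
        assert string_similarity("cancer", "cancer") == 1.0
        assert string_similarity("Breast  Cancer", "breast cancer") == 1.0

    def test_single_edit_worked_pair(self):
        assert string_similarity("tumour", "tumor") == pytest.approx(5 / 6)

    def test_unrelated_strings_low(self):
        assert string_similarity("asthma", "weather") < 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            string_similarity("", "x")
        with pytest.raises(ValueError):
            string_similarity("x", "   ")

    @given(
        st.text(alphabet=string.ascii_lowercase + " äöüè", min_size=1, max_size=20),
        st.text(alphabet=string.ascii_lowercase + " äöüè", min_size=1, max_size=20),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_edlib_oracle(self, a, b):
        from phir.ontology import normalize_term

        if not normalize_term(a) or not normalize_term(b):
            return
        assert string_similarity(a, b) == pytest.approx(oracle_similarity(a, b))
        assert string_similarity(a, b) == pytest.approx(string_similarity(b, a))

    def test_banded_levenshtein_cutoff_consistent(self):
        rng = random.Random(3)
        for _ in range(200):
            a = "".join(rng.choice("abcde") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("abcde") for _ in range(rng.randint(1, 12)))
            true_d = edlib.align(a, b)["editDistance"]
            for k in (0, 1, 2, 5):
                got = levenshtein(a, b, max_dist=k)
                assert got == (true_d if true_d <= k else k + 1)


class TestMatchConcepts:
    def test_fuzzy_match_above_threshold(self, small_ontology):
        anns = match_concepts(["tumour"], small_ontology, "en", threshold=0.8)
        assert [(a.concept_id, a.matched_term) for a in anns] == [("C2", "tumor")]
        assert anns[0].similarity == pytest.approx(5 / 6)

    def test_threshold_cut(self, small_ontology):
        assert match_concepts(["tumour"], small_ontology, "en", threshold=0.9) == []

    def test_ambiguous_term_yields_all_concepts(self, small_ontology):
        anns = match_concepts(["asthma"], small_ontology, "en", threshold=1.0)
        assert [a.concept_id for a in anns] == ["C4", "C5"]  # tie broken by id

    def test_no_annotation_below_threshold(self, small_ontology):
        for tau in (0.7, 0.85, 1.0):
            anns = match_concepts(
                ["tumour", "chemotherapyx", "weather"], small_ontology, "en", threshold=tau
            )
            assert all(a.similarity >= tau for a in anns)

    def test_raising_threshold_never_adds_annotations(self, small_ontology):
        cands = ["tumour", "asthmaa", "chemotherapy", "breast cancer"]
        previous = None
        for tau in (0.6, 0.7, 0.8, 0.9, 1.0):
            keys = {
                (a.concept_id, a.source_text)
                for a in match_concepts(cands, small_ontology, "en", threshold=tau)
            }
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_exact_plants_recovered_at_tau_1(self, generated_corpus):
        """tau=1.0 on an exact-plant corpus recovers exactly the planted
        concept sets (plant manifest is the oracle)."""
        tmp_path, onto_manifest, corpus_manifest = generated_corpus
        from phir import load_concept_table

        index = load_concept_table(tmp_path / "concepts.tsv")
        for doc, plants in corpus_manifest.plants.items():
            text = extract_text((tmp_path / doc).read_bytes(), "text/html")
            anns = annotate_document(
                text, (), index, "en", config=PhirConfig(similarity_threshold=1.0)
            )
            assert {a.concept_id for a in anns} >= corpus_manifest.planted_concepts(doc)


class TestCandidateStrings:
    def test_multiword_window_contains_phrase(self):
        records = get_tagger().tag("signs of breast cancer appear", "en")
        cands = candidate_strings(records)
        assert "breast cancer" in cands
        assert "breast" in cands and "cancer" in cands


class TestRegister:
    def test_video_entry_gets_tag_annotations_only(self, small_ontology, tmp_path):
        store = DocumentStore()
        entry = RegistrationEntry(
            url="http://videos.example.com/v1",
            title="chemo explained",
            doc_type="video",
            language="en",
            tags=("chemotherapy",),
        )
        docs = register(entry, small_ontology, store, fetcher=LocalDirectoryFetcher(tmp_path))
        assert len(docs) == 1
        assert [(a.concept_id, a.origin) for a in docs[0].annotations] == [("C3", "tag")]

    def test_text_entry_crawls_site_and_shares_metadata(self, small_ontology, tmp_path):
        site = generate_site(5, 0, seed=4, out_dir=tmp_path)
        f = LocalDirectoryFetcher(tmp_path, host=site.host)
        store = DocumentStore()
        entry = RegistrationEntry(
            url=f.url_for("index.html"),
            title="patient info site",
            doc_type="text",
            language="en",
        )
        docs = register(entry, small_ontology, store, fetcher=f)
        assert len(docs) == 5 == len(store)
        assert {d.entry.title for d in docs} == {"patient info site"}
        assert {d.entry.language for d in docs} == {"en"}

    def test_reregistration_is_idempotent(self, small_ontology, tmp_path):
        site = generate_site(3, 0, seed=5, out_dir=tmp_path)
        f = LocalDirectoryFetcher(tmp_path, host=site.host)
        store = DocumentStore()
        entry = RegistrationEntry(
            url=f.url_for("index.html"), title="t", doc_type="text", language="en"
        )
        first = register(entry, small_ontology, store, fetcher=f)
        second = register(entry, small_ontology, store, fetcher=f)
        assert len(store) == len(first) == len(second)

    def test_unreachable_url_stores_nothing(self, small_ontology, tmp_path):
        store = DocumentStore()
        entry = RegistrationEntry(
            url="http://example.org/absent.html", title="t", doc_type="text", language="en"
        )
        with pytest.raises(RegistrationError):
            register(entry, small_ontology, store, fetcher=LocalDirectoryFetcher(tmp_path))
        assert len(store) == 0

    def test_store_round_trips_through_jsonl(self, small_ontology, tmp_path):
        site = generate_site(2, 0, seed=6, out_dir=tmp_path / "site")
        f = LocalDirectoryFetcher(tmp_path / "site", host=site.host)
        store = DocumentStore()
        entry = RegistrationEntry(
            url=f.url_for("index.html"),
            title="t",
            doc_type="text",
            language="en",
            tags=("chemotherapy",),
        )
        register(entry, small_ontology, store, fetcher=f)
        path = tmp_path / "docs.jsonl"
        store.save(path)
        reloaded = DocumentStore.load(path)
        assert [d.to_json_dict() for d in reloaded.documents()] == [
            d.to_json_dict() for d in store.documents()
        ]

    def test_annotation_cap_respected(self):
        words = [
            f"term{a}{b}"
            for a in "abcdefghij"
            for b in "abcdefgh"
        ]  # 80 distinct alphabetic terms
        index = build_index(
            [Concept(f"C{i}", w, "en") for i, w in enumerate(words)]
        )
        text = " ".join(words)
        config = PhirConfig(similarity_threshold=1.0, max_annotations_per_doc=50)
        anns = annotate_document(text, (), index, "en", config=config)
        assert len(anns) == 50
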