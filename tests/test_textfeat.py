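"""Derailment, incoherence, adjective profiles, and transcript I/O."""

import math

import numpy as np
import pytest

from szspeech.textfeat import (
    AdjectiveProfile,
    AnnotatedResponse,
    AnnotatedToken,
    EmbeddingTable,
    EmptyCorpusError,
    build_adjective_profile,
    content_filter,
    cosine,
    derailment,
    incoherence,
    read_conllu,
    write_conllu,
)
from conftest import response, token, toy_embeddings  # noqa: F401


def derailment_oracle(vectors, k):
    """Brute-force enumeration of all (i, j) windowed cosine pairs."""
    n = len(vectors)
    word_scores = []
    for i in range(n):
        sims = []
        for j in range(i + 1, min(i + k, n - 1) + 1):
            sims.append(cosine(vectors[i], vectors[j]))
        if sims:
            word_scores.append(sum(sims) / len(sims))
    return sum(word_scores) / len(word_scores)


def amod_response(pairs, rid="r1"):
    """Build a response of ADJ->NOUN amod pairs."""
    tokens = []
    for noun, adj in pairs:
        i = len(tokens)
        tokens.append(AnnotatedToken(adj, adj, "ADJ", head=i + 1, deprel="amod"))
        tokens.append(AnnotatedToken(noun, noun, "NOUN", head=None, deprel="root"))
    return AnnotatedResponse(response_id=rid, participant_id="p1", tokens=tokens)


class TestContentFilter:
    def test_drops_function_words(self):
        resp = response([("sun", "NOUN"), ("the", "DET"), ("bright", "ADJ")])
        lemmas = [l for l, _ in content_filter(resp)]
        assert lemmas == ["sun", "bright"]

    def test_all_function_words(self):
        resp = response([("the", "DET"), ("of", "ADP")])
        assert content_filter(resp) == []

    def test_mixed_sentence_order_preserved(self):
        resp = response(
            [
                ("the", "DET"),
                ("sun", "NOUN"),
                ("shines", "VERB"),
                ("very", "ADV"),
                ("bright", "ADJ"),
                ("!", "PUNCT"),
            ]
        )
        lemmas = [l for l, _ in content_filter(resp)]
        assert lemmas == ["sun", "shines", "very", "bright"]

    def test_oov_dropped_with_embeddings(self, toy_embeddings):
        resp = response([("sun", "NOUN"), ("unknownword", "NOUN"), ("moon", "NOUN")])
        lemmas = [l for l, _ in content_filter(resp, toy_embeddings)]
        assert lemmas == ["sun", "moon"]


class TestDerailment:
    def test_identical_vectors_score_one(self):
        emb = EmbeddingTable({f"w{i}": np.array([2.0, 1.0]) for i in range(5)})
        resp = response([(f"w{i}", "NOUN") for i in range(5)])
        for k in range(1, 7):
            assert derailment(resp, emb, k) == pytest.approx(1.0)

    def test_orthogonal_pair_k1(self, toy_embeddings):
        resp = response([("sun", "NOUN"), ("moon", "NOUN")])
        assert derailment(resp, toy_embeddings, 1) == pytest.approx(0.0)

    def test_three_words_k2_hand_value(self, toy_embeddings):
        # sun=(1,0), moon=(0,1), star=(1,1)
        # word0: mean(cos(sun,moon), cos(sun,star)) = (0 + 1/sqrt2)/2
        # word1: cos(moon, star) = 1/sqrt2
        resp = response([("sun", "NOUN"), ("moon", "NOUN"), ("star", "NOUN")])
        expected = ((0 + 1 / math.sqrt(2)) / 2 + 1 / math.sqrt(2)) / 2
        assert derailment(resp, toy_embeddings, 2) == pytest.approx(expected)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        words = [f"w{i}" for i in range(12)]
        emb = EmbeddingTable({w: rng.normal(size=6) for w in words})
        resp = response([(w, "NOUN") for w in words])
        for k in range(1, 7):
            expected = derailment_oracle([emb[w] for w in words], k)
            assert derailment(resp, emb, k) == pytest.approx(expected, abs=1e-12)

    def test_undefined_below_two_words(self, toy_embeddings):
        assert math.isnan(derailment(response([("sun", "NOUN")]), toy_embeddings, 1))

    def test_k_range_enforced(self, toy_embeddings):
        resp = response([("sun", "NOUN"), ("moon", "NOUN")])
        with pytest.raises(ValueError):
            derailment(resp, toy_embeddings, 7)


class TestAdjectiveProfile:
    def test_two_documents_same_pair(self):
        docs = [amod_response([("house", "good")], rid=f"d{i}") for i in range(2)]
        profile = build_adjective_profile(docs)
        assert profile.pairs == {"house": {"good": 2}}
        assert profile.corpus_document_count == 2

    def test_document_without_pairs_counts_toward_n(self):
        docs = [
            amod_response([("house", "good")]),
            response([("run", "VERB")], rid="d2"),
        ]
        profile = build_adjective_profile(docs)
        assert profile.corpus_document_count == 2
        assert profile.pairs["house"]["good"] == 1

    def test_three_document_hand_enumeration(self):
        docs = [
            amod_response([("house", "good"), ("car", "fast")], rid="d1"),
            amod_response([("house", "good"), ("house", "big")], rid="d2"),
            amod_response([("car", "fast"), ("car", "fast")], rid="d3"),  # df, not count
        ]
        profile = build_adjective_profile(docs)
        assert profile.pairs == {
            "house": {"good": 2, "big": 1},
            "car": {"fast": 2},
        }
        assert profile.idf("house", "big") == pytest.approx(math.log(3))

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyCorpusError):
            build_adjective_profile([])

    def test_round_trip(self, tmp_path):
        profile = AdjectiveProfile(
            pairs={"house": {"good": 2, "big": 1}}, corpus_document_count=4
        )
        path = profile.write(tmp_path / "profile.tsv")
        back = AdjectiveProfile.read(path)
        assert back.pairs == profile.pairs
        assert back.corpus_document_count == 4


class TestIncoherence:
    def test_identical_single_adjective(self, toy_embeddings):
        # profile adjective == response adjective, df == N (idf 0 -> uniform)
        profile = AdjectiveProfile({"sun": {"bright": 2}}, corpus_document_count=2)
        resp = amod_response([("sun", "bright")])
        assert incoherence(resp, toy_embeddings, profile) == pytest.approx(1.0)

    def test_orthogonal_adjective(self, toy_embeddings):
        profile = AdjectiveProfile({"sun": {"bright": 1}}, corpus_document_count=3)
        resp = amod_response([("sun", "dark")])  # dark _|_ bright
        assert incoherence(resp, toy_embeddings, profile) == pytest.approx(0.0)

    def test_idf_weighted_aggregate_hand_value(self, toy_embeddings):
        # profile for "sun": bright (df 1), dark (df 2), corpus of 4 docs
        # idf: ln 4, ln 2 -> weights (ln4, ln2)/(ln4+ln2) = (2/3, 1/3)
        # aggregate = 2/3*(1,0) + 1/3*(0,1) = (2/3, 1/3)
        # response adjective warm = (3,4): cos = (2+4/3)/(5*sqrt(5)/3)
        profile = AdjectiveProfile(
            {"sun": {"bright": 1, "dark": 2}}, corpus_document_count=4
        )
        resp = amod_response([("sun", "warm")])
        agg = np.array([2 / 3, 1 / 3])
        expected = float(
            np.dot([3, 4], agg) / (5 * np.linalg.norm(agg))
        )
        assert incoherence(resp, toy_embeddings, profile) == pytest.approx(expected)

    def test_mean_over_pairs(self, toy_embeddings):
        profile = AdjectiveProfile(
            {"sun": {"bright": 1}, "moon": {"dark": 1}}, corpus_document_count=3
        )
        resp = amod_response([("sun", "bright"), ("moon", "bright")])
        # pair 1 scores 1.0; pair 2 scores cos(bright, dark) = 0
        assert incoherence(resp, toy_embeddings, profile) == pytest.approx(0.5)

    def test_unknown_noun_skipped(self, toy_embeddings):
        profile = AdjectiveProfile({"sun": {"bright": 1}}, corpus_document_count=2)
        resp = amod_response([("galaxy", "bright")])
        assert math.isnan(incoherence(resp, toy_embeddings, profile))

    def test_invariant_under_corpus_duplication(self, toy_embeddings):
        docs = [
            amod_response([("sun", "bright"), ("moon", "dark")], rid="d1"),
            amod_response([("sun", "warm")], rid="d2"),
        ]
        resp = amod_response([("sun", "dark")])
        once = incoherence(resp, toy_embeddings, build_adjective_profile(docs))
        doubled = build_adjective_profile(
            docs + [AnnotatedResponse(f"{d.response_id}x", "corpus", d.tokens) for d in docs]
        )
        assert incoherence(resp, toy_embeddings, doubled) == pytest.approx(once, abs=1e-12)


class TestConlluIO:
    def test_round_trip(self, tmp_path):
        resp = amod_response([("house", "good"), ("car", "fast")], rid="r7")
        path = write_conllu(resp, tmp_path / "p1_r7.conllu")
        back = read_conllu(path)
        assert back.response_id == "r7"
        assert back.participant_id == "p1"
        assert [t.lemma for t in back.tokens] == ["good", "house", "fast", "car"]
        assert back.amod_pairs() == [("house", "good"), ("car", "fast")]

    def test_skips_multiword_ranges_and_comments(self, tmp_path):
        text = (
            "# participant_id = s9\n"
            "# response_id = r2\n"
            "1-2\tdella\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tbig\tbig\tADJ\t_\t_\t2\tamod\t_\t_\n"
            "2\tdog\tdog\tNOUN\t_\t_\t0\troot\t_\t_\n"
            "\n"
            "1\truns\trun\tVERB\t_\t_\t0\troot\t_\t_\n"
        )
        p = tmp_path / "x.conllu"
        p.write_text(text)
        resp = read_conllu(p)
        assert resp.participant_id == "s9"
        assert len(resp.tokens) == 3
        assert resp.amod_pairs() == [("dog", "big")]
        # head indices rebased across sentences
        assert resp.tokens[2].head is None


class TestEmbeddingIO:
    def test_word2vec_round_trip(self, tmp_path):
        emb = EmbeddingTable(
            {"alpha": np.array([1.0, 2.0, 3.0]), "Beta": np.array([-1.0, 0.5, 0.0])}
        )
        path = emb.write_word2vec(tmp_path / "emb.vec")
        first = path.read_text().splitlines()[0]
        assert first == "2 3"
        back = EmbeddingTable.read_word2vec(path)
        assert "BETA" in back  # case-normalized lookup
        np.testing.assert_allclose(back["beta"], [-1.0, 0.5, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingTable({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
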