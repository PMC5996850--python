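import math
import random

import pytest

from phrasemine.candidate_extraction import CandidateString
from phrasemine.corpus_io import Document, DocumentCollection
from phrasemine.retrieval_filter import (
    NEGATIVE,
    POSITIVE,
    BM25Params,
    EvaluationConfig,
    JudgedSet,
    PhraseEvaluation,
    ZeroPositivesError,
    ap_from_scores,
    average_precision,
    bm25_phrase_score,
    bm25_word_score,
    build_judged_set,
    evaluate_phrase,
    random_baseline_ap,
    rank_and_ap,
    relative_improvement,
    select_subset,
)
from phrasemine.stats_index import build_index


class _StubIndex:
    """Minimal duck-typed index with fixed statistics, for formula-level
    BM25 checks."""

    def __init__(self, n_docs, avgdl, word_df, word_tf, doc_len):
        self.n_docs = n_docs
        self.avgdl = avgdl
        self._df = word_df
        self._tf = word_tf
        self._len = doc_len

    def doc_freq(self, unit):
        key = unit if isinstance(unit, str) else " ".join(unit)
        return self._df.get(key, 0)

    def tf(self, doc_id, unit):
        key = unit if isinstance(unit, str) else " ".join(unit)
        return self._tf.get((doc_id, key), 0)

    def abstract_len(self, doc_id):
        return self._len[doc_id]


class TestBM25:
    def test_word_score_formula(self):
        # D=100, df=10, tf=1, dl=avgdl -> score = ln(90.5/10.5)
        index = _StubIndex(
            n_docs=100, avgdl=50.0, word_df={"zinc": 10}, word_tf={("d1", "zinc"): 1},
            doc_len={"d1": 50},
        )
        score = bm25_word_score("d1", ["zinc"], index)
        assert score == pytest.approx(math.log(90.5 / 10.5), rel=1e-12)
        assert score == pytest.approx(2.154, abs=5e-4)

    def test_absent_word_contributes_zero(self):
        index = _StubIndex(100, 50.0, {"zinc": 10, "finger": 5}, {("d1", "zinc"): 1}, {"d1": 50})
        only_zinc = bm25_word_score("d1", ["zinc"], index)
        both = bm25_word_score("d1", ["zinc", "finger"], index)
        assert both == only_zinc

    def test_phrase_score_zero_without_contiguity(self):
        coll = DocumentCollection(
            documents=[
                Document.from_text("1", "T.", "Zinc binds the finger domain."),
                Document.from_text("2", "T.", "The zinc finger domain."),
                Document.from_text("3", "T.", "Unrelated filler text here."),
                Document.from_text("4", "T.", "More filler sentences follow."),
            ]
        )
        index = build_index(coll)
        phrase = CandidateString(tokens=("zinc", "finger"))
        assert bm25_phrase_score("1", phrase, index) == 0.0
        assert bm25_phrase_score("2", phrase, index) > 0.0

    def test_phrase_score_saturates_at_idf_times_k1_plus_1(self):
        params = BM25Params()
        idf = math.log((100 - 5 + 0.5) / (5 + 0.5))
        scores = []
        for tf in (1, 5, 50, 5000):
            index = _StubIndex(
                100, 50.0, {"a b": 5}, {("d1", "a b"): tf}, {"d1": 50}
            )
            scores.append(bm25_phrase_score("d1", CandidateString(tokens=("a", "b")), index, params))
        assert scores == sorted(scores)
        assert scores[-1] < idf * (params.k1 + 1)
        assert scores[-1] == pytest.approx(idf * (params.k1 + 1), rel=1e-2)

    def test_length_normalization_cancels_at_avgdl(self):
        # tf=1 and dl=avgdl: score reduces exactly to idf
        index = _StubIndex(100, 50.0, {"a b": 5}, {("d1", "a b"): 1}, {"d1": 50})
        idf = math.log((100 - 5 + 0.5) / (5 + 0.5))
        score = bm25_phrase_score("d1", CandidateString(tokens=("a", "b")), index)
        assert score == pytest.approx(idf, rel=1e-12)

    def test_idf_floor_applies(self):
        # df > D/2 makes raw idf negative; the floor clips it
        index = _StubIndex(10, 50.0, {"zinc": 9}, {("d1", "zinc"): 1}, {"d1": 50})
        assert bm25_word_score("d1", ["zinc"], index, BM25Params(idf_floor=0.0)) == 0.0
        assert bm25_word_score("d1", ["zinc"], index, BM25Params(idf_floor=0.5)) > 0.0


class TestAveragePrecision:
    def test_interleaved_ranking(self):
        assert average_precision([True, False, True]) == pytest.approx(5 / 6)

    def test_perfect_ranking(self):
        assert average_precision([True, True, False, False]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 7
        labels = [False] * (n - 1) + [True]
        assert average_precision(labels) == pytest.approx(1 / n)

    def test_zero_positives_signaled(self):
        with pytest.raises(ZeroPositivesError):
            average_precision([False, False])

    def test_ties_broken_by_ascending_doc_id(self):
        scores = {"b": 1.0, "a": 1.0, "c": 1.0}
        # ranking is a, b, c regardless of dict order
        assert ap_from_scores(scores, {"a"}) == 1.0
        assert ap_from_scores(scores, {"c"}) == pytest.approx(1 / 3)


class TestRandomBaseline:
    def test_all_positives_is_one(self):
        assert random_baseline_ap(3, 3) == 1.0

    def test_one_of_two_by_enumeration(self):
        # orderings: pos first (AP 1) or second (AP 1/2)
        assert random_baseline_ap(1, 2) == pytest.approx(0.75)

    def test_monte_carlo_close_to_enumeration(self):
        exact = random_baseline_ap(2, 6, method="exact")
        mc = random_baseline_ap(2, 6, reps=10_000, seed=5, method="mc")
        assert mc == pytest.approx(exact, abs=0.02)

    def test_monte_carlo_is_seeded(self):
        a = random_baseline_ap(3, 20, reps=500, seed=9, method="mc")
        b = random_baseline_ap(3, 20, reps=500, seed=9, method="mc")
        assert a == b

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            random_baseline_ap(0, 5)
        with pytest.raises(ValueError):
            random_baseline_ap(6, 5)


@pytest.fixture
def labeled_collection():
    """'breast cancer treatments' in both title+abstract (positive), only in
    the abstract (negative), partially in the title (negative), and with a
    missing word (excluded)."""
    rows = [
        ("1", "Advances in breast cancer treatments.", "New breast cancer treatments are reviewed."),
        ("2", "A clinical overview.", "Breast cancer treatments were compared in trials."),
        ("3", "Breast cancer epidemiology.", "Treatments for breast cancer vary widely."),
        ("4", "Cancer treatments today.", "Cancer treatments are evolving rapidly."),
    ]
    return DocumentCollection(documents=[Document.from_text(i, t, a) for i, t, a in rows])


class TestJudgedSets:
    def test_title_based_labels(self, labeled_collection):
        index = build_index(labeled_collection)
        phrase = CandidateString(tokens=("breast", "cancer", "treatments"))
        judged = build_judged_set(phrase, index)
        labels = dict(judged.docs)
        assert labels["1"] == POSITIVE
        assert labels["2"] == NEGATIVE  # words only in the abstract
        assert labels["3"] == NEGATIVE  # title holds 2 of 3 words: conservative
        assert "4" not in labels  # abstract lacks 'breast'
        assert judged.n_pos == 1 and judged.n_total == 3

    def test_rank_and_ap_requires_a_positive(self, labeled_collection):
        index = build_index(labeled_collection)
        phrase = CandidateString(tokens=("cancer", "treatments"))
        judged = build_judged_set(phrase, index)
        judged.docs = [(d, NEGATIVE) for d, _ in judged.docs]
        with pytest.raises(ZeroPositivesError):
            rank_and_ap(judged, "word", index)


def _evaluation(n_pos=6, n_total=10, ap_word=0.2, ap_phrase=0.3, ap_random=0.25,
                criteria=None, tokens=("x", "y")):
    if criteria is None:
        criteria = (n_pos >= 5, ap_phrase > ap_word, ap_phrase > ap_random, ap_word > 0.01)
    return PhraseEvaluation(
        phrase=CandidateString(tokens=tokens),
        n_pos=n_pos, n_total=n_total,
        ap_word=ap_word, ap_phrase=ap_phrase, ap_random=ap_random,
        criteria_passed=tuple(criteria),
    )


class TestCriteriaAndSelection:
    def test_relative_improvement_arithmetic(self):
        assert relative_improvement(0.20, 0.21) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            relative_improvement(0.0, 0.5)

    def test_too_few_common_documents_fails_first_criterion(self):
        ev = _evaluation(n_pos=4)
        assert not ev.criteria_passed[0] and not ev.selected

    def test_low_word_ap_fails_fourth_criterion(self):
        ev = _evaluation(ap_word=0.005, ap_phrase=0.4)
        assert not ev.criteria_passed[3] and not ev.selected

    def test_selection_requires_all_four(self):
        assert _evaluation().selected
        for i in range(4):
            flags = [True] * 4
            flags[i] = False
            assert not _evaluation(criteria=flags).selected

    def test_small_subset_excludes_modest_improvement(self):
        modest = _evaluation(ap_word=0.20, ap_phrase=0.21, ap_random=0.05, tokens=("m", "m2"))
        strong = _evaluation(ap_word=0.20, ap_phrase=0.30, ap_random=0.05, tokens=("s", "s2"))
        full = select_subset([modest, strong], min_improvement=0.0)
        small = select_subset([modest, strong], min_improvement=0.10)
        assert {e.phrase.tokens for e in full} == {("m", "m2"), ("s", "s2")}
        assert {e.phrase.tokens for e in small} == {("s", "s2")}

    def test_select_subset_antitone_in_threshold(self):
        rng = random.Random(1)
        evals = [
            _evaluation(
                ap_word=0.1 + 0.3 * rng.random(),
                ap_phrase=0.1 + 0.5 * rng.random(),
                ap_random=0.05,
                tokens=(f"t{i}", "z"),
            )
            for i in range(40)
        ]
        prev = None
        for thr in (0.0, 0.05, 0.10, 0.25, 0.5):
            cur = {e.phrase.tokens for e in select_subset(evals, min_improvement=thr)}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_evaluate_phrase_zero_positive_pool(self, labeled_collection):
        index = build_index(labeled_collection)
        # words present in abstracts but never together in a title
        ev = evaluate_phrase(CandidateString(tokens=("reviewed", "new")), index)
        assert ev.n_pos == 0 and ev.ap_word is None and not ev.selected

    def test_planted_phrase_passes_all_criteria(self, study):
        collection, truth = study["collection"], study["truth"]
        index = build_index(collection)
        config = EvaluationConfig(seed=3)
        toks = sorted(truth.planted)[0]
        ev = evaluate_phrase(CandidateString(tokens=toks), index, config)
        assert ev.criteria_passed == (True, True, True, True)
        assert ev.selected and ev.improvement > 0
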