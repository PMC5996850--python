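"""BM25-based retrieval filtering of segmented phrases.

Each statistically coherent phrase is treated as a query. Its candidate
pool is every document whose abstract contains all the phrase's words in
any positions; a document is a pseudo-relevant positive (set T) when its
title also contains all the words, and a negative (set A) otherwise —
including titles carrying only some of the words (conservative rule).
Abstracts are then ranked twice with Okapi BM25: once scoring the
individual words, once scoring the phrase as a single multi-word term whose
term frequency and document frequency count only contiguous occurrences.
Ranking quality is summarized by average precision (AP) against the T/A
labels. A phrase is kept when (1) |T| >= 5, (2) phrase-based AP strictly
exceeds word-based AP, (3) phrase-based AP exceeds the expected AP of a
random ranking of the same pool, and (4) word-based AP exceeds 0.01.

The BM25 constants are the standard Okapi defaults (k1=1.2, b=0.75); the
comparison is between two scorers under identical constants, so the
contrast is insensitive to their exact values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .candidate_extraction import CandidateString
from .stats_index import CorpusIndex

POSITIVE = "T"
NEGATIVE = "A"

DEFAULT_MIN_POS = 5
DEFAULT_AP_WORD_FLOOR = 0.01
DEFAULT_BASELINE_REPS = 1000
EXACT_ENUMERATION_MAX = 8


class ZeroPositivesError(ValueError):
    """Average precision is undefined for a judged set with no positives."""


@dataclass(frozen=True)
class BM25Params:
    k1: float = 1.2
    b: float = 0.75
    idf_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or not 0.0 <= self.b <= 1.0 or self.idf_floor < 0:
            raise ValueError("invalid BM25 parameters")


@dataclass(frozen=True)
class EvaluationConfig:
    """Tunables of the retrieval filter."""

    params: BM25Params = BM25Params()
    min_pos: int = DEFAULT_MIN_POS
    ap_word_floor: float = DEFAULT_AP_WORD_FLOOR
    baseline_reps: int = DEFAULT_BASELINE_REPS
    seed: int = 0


@dataclass
class JudgedSet:
    """The pool A∪T for a phrase-query with its pseudo-relevance labels."""

    phrase: CandidateString
    docs: list[tuple[str, str]]  # (doc_id, POSITIVE | NEGATIVE), doc_id ascending

    @property
    def n_pos(self) -> int:
        return sum(1 for _, lab in self.docs if lab == POSITIVE)

    @property
    def n_total(self) -> int:
        return len(self.docs)


@dataclass
class PhraseEvaluation:
    """Per-phrase retrieval evidence and the four criterion flags."""

    phrase: CandidateString
    n_pos: int
    n_total: int
    ap_word: float | None
    ap_phrase: float | None
    ap_random: float | None
    criteria_passed: tuple[bool, bool, bool, bool]

    @property
    def improvement(self) -> float | None:
        """Relative AP improvement of phrase- over word-based ranking;
        defined only when word-based AP is positive."""
        if not self.ap_word or self.ap_phrase is None:
            return None
        return (self.ap_phrase - self.ap_word) / self.ap_word

    @property
    def selected(self) -> bool:
        return all(self.criteria_passed)


def relative_improvement(ap_word: float, ap_phrase: float) -> float:
    """(AP_phrase - AP_word) / AP_word — the relative gain reported for a
    phrase set."""
    if ap_word <= 0:
        raise ValueError("relative improvement undefined for ap_word <= 0")
    return (ap_phrase - ap_word) / ap_word


def build_judged_set(phrase: CandidateString, index: CorpusIndex) -> JudgedSet:
    """Label every document whose abstract contains all phrase words:
    positive (T) iff the title also contains them all, negative (A)
    otherwise."""
    words = set(phrase.tokens)
    docs = [
        (doc_id, POSITIVE if index.title_contains_all(doc_id, words) else NEGATIVE)
        for doc_id in index.docs_with_all_words(words)
    ]
    return JudgedSet(phrase=phrase, docs=docs)


def _idf(df: int, n_docs: int, floor: float) -> float:
    return max(floor, math.log((n_docs - df + 0.5) / (df + 0.5)))


def _bm25_term(tf: int, idf: float, dl: int, avgdl: float, params: BM25Params) -> float:
    if tf == 0:
        return 0.0
    norm = params.k1 * (1.0 - params.b + params.b * dl / avgdl)
    return idf * tf * (params.k1 + 1.0) / (tf + norm)


def bm25_word_score(
    doc_id: str, words: Sequence[str], index: CorpusIndex, params: BM25Params = BM25Params()
) -> float:
    """Okapi BM25 score of a document's abstract for the individual words
    (sum of per-word contributions)."""
    dl = index.abstract_len(doc_id)
    return sum(
        _bm25_term(
            index.tf(doc_id, w),
            _idf(index.doc_freq(w), index.n_docs, params.idf_floor),
            dl,
            index.avgdl,
            params,
        )
        for w in words
    )


def bm25_phrase_score(
    doc_id: str,
    phrase: CandidateString,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> float:
    """BM25 score treating the phrase as a single multi-word term: tf counts
    contiguous occurrences in the abstract, df counts documents containing
    the phrase contiguously."""
    tf = index.tf(doc_id, phrase.tokens)
    if tf == 0:
        return 0.0
    idf = _idf(index.doc_freq(phrase.tokens), index.n_docs, params.idf_floor)
    return _bm25_term(tf, idf, index.abstract_len(doc_id), index.avgdl, params)


def average_precision(labels_in_rank_order: Sequence[bool]) -> float:
    """AP of a ranked label sequence: mean over relevant ranks of
    (relevant seen so far) / rank."""
    hits = 0
    precisions = []
    for rank, rel in enumerate(labels_in_rank_order, start=1):
        if rel:
            hits += 1
            precisions.append(hits / rank)
    if not precisions:
        raise ZeroPositivesError("no positive documents in ranking")
    return sum(precisions) / len(precisions)


def ap_from_scores(scores: Mapping[str, float], positives: Iterable[str]) -> float:
    """AP of the ranking induced by ``scores`` (descending; ties broken by
    ascending doc id) against the given positive ids."""
    pos = set(positives)
    ranked = sorted(scores, key=lambda d: (-scores[d], d))
    return average_precision([d in pos for d in ranked])


def rank_and_ap(
    judged: JudgedSet,
    scorer: Literal["word", "phrase"],
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> float:
    """Rank the judged pool by BM25 score (descending; ties broken by
    ascending doc_id) and return the average precision of the T labels."""
    if judged.n_pos == 0:
        raise ZeroPositivesError(f"judged set for {judged.phrase.text!r} has no positives")
    if scorer == "word":
        scores = {
            d: bm25_word_score(d, judged.phrase.tokens, index, params) for d, _ in judged.docs
        }
    elif scorer == "phrase":
        scores = {d: bm25_phrase_score(d, judged.phrase, index, params) for d, _ in judged.docs}
    else:
        raise ValueError(f"unknown scorer {scorer!r}")
    return ap_from_scores(scores, (d for d, lab in judged.docs if lab == POSITIVE))


@lru_cache(maxsize=4096)
def _exact_random_ap(n_pos: int, n_total: int) -> float:
    """Exact expected AP of a uniformly random ranking, by enumerating all
    placements of the positive ranks (each equally likely)."""
    total = 0.0
    count = 0
    for positions in combinations(range(1, n_total + 1), n_pos):
        hits = 0
        ap = 0.0
        for i, rank in enumerate(positions, start=1):
            hits = i
            ap += hits / rank
        total += ap / n_pos
        count += 1
    return total / count


def random_baseline_ap(
    n_pos: int,
    n_total: int,
    reps: int = DEFAULT_BASELINE_REPS,
    seed: int = 0,
    method: Literal["auto", "exact", "mc"] = "auto",
) -> float:
    """Expected AP when the judged pool is ranked uniformly at random.

    Exact enumeration for pools of up to 8 documents; otherwise a seeded
    Monte Carlo mean over ``reps`` random permutations. ``method`` can force
    either estimator (exact enumeration grows combinatorially).
    """
    if not 1 <= n_pos <= n_total:
        raise ValueError("need 1 <= n_pos <= n_total")
    if n_pos == n_total:
        return 1.0
    if method == "exact" or (method == "auto" and n_total <= EXACT_ENUMERATION_MAX):
        return _exact_random_ap(n_pos, n_total)
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_total, dtype=bool)
    labels[:n_pos] = True
    # vectorized: one random permutation per row
    keys = rng.random((reps, n_total))
    perms = np.argsort(keys, axis=1)
    shuffled = labels[perms]
    ranks = np.arange(1, n_total + 1, dtype=float)
    cum = np.cumsum(shuffled, axis=1)
    ap = np.where(shuffled, cum / ranks, 0.0).sum(axis=1) / n_pos
    return float(ap.mean())


def evaluate_phrase(
    phrase: CandidateString,
    index: CorpusIndex,
    config: EvaluationConfig = EvaluationConfig(),
) -> PhraseEvaluation:
    """Assemble the judged pool, compute both rankings, the random baseline,
    and the four criterion flags. A phrase is selected iff all four hold."""
    judged = build_judged_set(phrase, index)
    n_pos, n_total = judged.n_pos, judged.n_total
    if n_pos == 0:
        return PhraseEvaluation(
            phrase=phrase,
            n_pos=0,
            n_total=n_total,
            ap_word=None,
            ap_phrase=None,
            ap_random=None,
            criteria_passed=(False, False, False, False),
        )
    ap_word = rank_and_ap(judged, "word", index, config.params)
    ap_phrase = rank_and_ap(judged, "phrase", index, config.params)
    ap_random = random_baseline_ap(
        n_pos, n_total, reps=config.baseline_reps, seed=config.seed
    )
    criteria = (
        n_pos >= config.min_pos,
        ap_phrase > ap_word,
        ap_phrase > ap_random,
        ap_word > config.ap_word_floor,
    )
    return PhraseEvaluation(
        phrase=phrase,
        n_pos=n_pos,
        n_total=n_total,
        ap_word=ap_word,
        ap_phrase=ap_phrase,
        ap_random=ap_random,
        criteria_passed=criteria,
    )


def select_subset(
    evaluations: Iterable[PhraseEvaluation], min_improvement: float = 0.0
) -> list[PhraseEvaluation]:
    """Phrases passing all four criteria whose relative improvement is at
    least ``min_improvement`` (0 reproduces the full selected set; 0.10
    gives the high-improvement subset)."""
    out = []
    for ev in evaluations:
        if ev.selected and ev.improvement is not None and ev.improvement >= min_improvement:
            out.append(ev)
    return out
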