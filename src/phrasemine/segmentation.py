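"""Chained hypergeometric segmentation of candidate strings.

Under the null hypothesis that two units land in sentences independently,
the number of sentences Y containing both, given that unit 1 is in N_s of
the N corpus sentences and unit 2 in N_t, is hypergeometric:

    P(Y = y) = C(N_t, y) C(N - N_t, N_s - y) / C(N, N_s)

The observed statistic is deliberately stricter than co-membership: N'_st
counts only sentences containing the two units *adjacent as a phrase*, and
the p-value is the upper tail sum of P(Y = y) for y from N'_st to
min(N_s, N_t). Because N'_st <= N_st, this substitution can only make the
test more stringent.

A candidate of k words is tested left to right: step i tests the contiguous
chunk w_1..w_i (its contiguous-sentence count as N_s) against word w_{i+1}
(its word sentence count as N_t), with N'_st the contiguous count of the
extended chunk. A candidate is a coherent unit iff every step's p-value is
at or below the threshold (default 0.01). Since each candidate entails
several tests, a Benjamini-Hochberg step-up correction is applied within
each candidate's family of step p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .candidate_extraction import CandidateString
from .stats_index import CorpusIndex

DEFAULT_ALPHA = 0.01
DEFAULT_BH_Q = 0.01

ACCEPTED = "accepted"
DISCARDED = "discarded"
BH_ELIMINATED = "bh_eliminated"


@dataclass(frozen=True)
class CooccurrenceStats:
    """Sentence counts feeding one hypergeometric test.

    ``n``: total sentences; ``n_s``: sentences containing unit 1; ``n_t``:
    sentences containing unit 2; ``n_st_phrase``: sentences containing the
    contiguous concatenation (the stringent N'_st statistic).
    """

    n: int
    n_s: int
    n_t: int
    n_st_phrase: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_st_phrase <= min(self.n_s, self.n_t) <= self.n):
            raise ValueError(
                f"invalid co-occurrence stats: N={self.n}, Ns={self.n_s}, "
                f"Nt={self.n_t}, N'st={self.n_st_phrase}"
            )


def hypergeom_pmf(y: int, stats: CooccurrenceStats) -> float:
    """P(Y = y) under the independence null; 0 outside the support."""
    lo = max(0, stats.n_s + stats.n_t - stats.n)
    hi = min(stats.n_s, stats.n_t)
    if y < lo or y > hi:
        return 0.0
    return float(hypergeom.pmf(y, stats.n, stats.n_t, stats.n_s))


def hypergeom_pvalue(stats: CooccurrenceStats) -> float:
    """Upper-tail probability P(Y >= N'_st); 1.0 when N'_st is 0."""
    if stats.n_st_phrase <= 0:
        return 1.0
    p = float(hypergeom.sf(stats.n_st_phrase - 1, stats.n, stats.n_t, stats.n_s))
    return min(max(p, 0.0), 1.0)


@dataclass
class SegmentationStep:
    """One chained test: the chunk so far, the next word, and the p-value."""

    prefix: str
    next_word: str
    p_value: float
    stats: CooccurrenceStats | None = None


@dataclass
class SegmentationTrace:
    """A candidate with its ordered chain of step p-values and the outcome
    (accepted, discarded at some step, or eliminated by the BH correction)."""

    candidate: CandidateString
    steps: list[SegmentationStep] = field(default_factory=list)
    outcome: str = DISCARDED
    failed_step: int | None = None  # 1-based index of the first failing step

    @property
    def step_pvalues(self) -> list[float]:
        return [s.p_value for s in self.steps]

    @property
    def accepted(self) -> bool:
        return self.outcome == ACCEPTED


def segment_candidate(
    candidate: CandidateString, index: CorpusIndex, alpha: float = DEFAULT_ALPHA
) -> SegmentationTrace:
    """Run the left-to-right chained hypergeometric test on one candidate.

    All k-1 step p-values are recorded; the candidate is accepted iff every
    one is <= ``alpha`` (a p-value exactly at the threshold passes). A
    candidate whose full string never occurs contiguously cannot be a
    coherent unit and is discarded.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    toks = candidate.tokens
    trace = SegmentationTrace(candidate=candidate)
    n = index.N
    for i in range(1, len(toks)):
        chunk = toks[:i]
        nxt = toks[i]
        stats = CooccurrenceStats(
            n=n,
            n_s=index.sentence_count(chunk),
            n_t=index.sentence_count(nxt),
            n_st_phrase=index.sentence_count(toks[: i + 1]),
        )
        p = hypergeom_pvalue(stats)
        trace.steps.append(
            SegmentationStep(prefix=" ".join(chunk), next_word=nxt, p_value=p, stats=stats)
        )
        if p > alpha and trace.failed_step is None:
            trace.failed_step = i
    trace.outcome = ACCEPTED if trace.failed_step is None else DISCARDED
    return trace


def bh_reject(p_values: Sequence[float], q: float) -> list[bool]:
    """Benjamini-Hochberg step-up: with p_(1) <= ... <= p_(m), reject all
    hypotheses of rank <= the largest k such that p_(k) <= k*q/m. Boundary
    comparisons are inclusive. Returns per-hypothesis rejection flags in the
    input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= q * rank / m:
            k_max = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            reject[idx] = True
    return reject


def bh_correct(trace: SegmentationTrace, q: float = DEFAULT_BH_Q) -> SegmentationTrace:
    """Apply the BH correction to the candidate's family of step p-values.

    If the candidate was accepted but some step is no longer rejected after
    the step-up procedure, the outcome becomes ``bh_eliminated``; otherwise
    the trace is unchanged.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if not trace.steps:
        raise ValueError("trace has no step p-values")
    if not trace.accepted:
        return trace
    if all(bh_reject(trace.step_pvalues, q)):
        return trace
    out = replace(trace)
    out.steps = list(trace.steps)
    out.outcome = BH_ELIMINATED
    return out


def segment_candidates(
    candidates: Iterable[CandidateString],
    index: CorpusIndex,
    alpha: float = DEFAULT_ALPHA,
    bh_q: float = DEFAULT_BH_Q,
) -> list[SegmentationTrace]:
    """Segment every candidate (deduplicated, deterministic order) and apply
    the BH correction to each accepted trace."""
    traces = []
    for cand in sorted(set(candidates), key=lambda c: c.tokens):
        traces.append(bh_correct(segment_candidate(cand, index, alpha=alpha), q=bh_q))
    return traces
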