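"""Candidate phrase harvesting.

Candidates are multi-word strings bounded by punctuation or stopwords:
within each sentence, maximal runs of non-stopword tokens between boundary
markers are located, and every contiguous sub-run of length >= 2 is counted
(nested phrases like 'heavy oil' inside 'super heavy oil' must be reachable,
so harvesting is not restricted to maximal runs). Strings seen fewer than
``min_count`` times are discarded. An external lexicon (one phrase per
line) can be merged in; its phrases may contain stopwords but must occur at
least once in the corpus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import BOUNDARY, DocumentCollection, TokenizerConfig, tokenize_and_split
from .stats_index import CorpusIndex, Tokens

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 5

HARVESTED = "harvested"
EXTERNAL = "external"


@dataclass(frozen=True)
class CandidateString:
    """A multi-word candidate: its tokens, corpus frequency (contiguous
    occurrences) and provenance. Identity is by tokens only, so a set of
    candidates deduplicates by string."""

    tokens: Tokens
    corpus_frequency: int = field(compare=False, default=0)
    source: str = field(compare=False, default=HARVESTED)

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError("candidates must have at least two tokens")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def _runs(sentence: list[str], stopwords: frozenset[str]):
    """Maximal runs of non-stopword tokens between boundaries/stopwords."""
    run: list[str] = []
    for tok in sentence:
        if tok == BOUNDARY or tok in stopwords:
            if len(run) >= 2:
                yield tuple(run)
            run = []
        else:
            run.append(tok)
    if len(run) >= 2:
        yield tuple(run)


def harvest_candidates(
    collection: DocumentCollection,
    config: TokenizerConfig | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> set[CandidateString]:
    """Harvest all multi-word strings bounded by punctuation or stopwords
    occurring at least ``min_count`` times (titles and abstracts both
    contribute). Every contiguous sub-run of length >= 2 of a maximal run is
    a candidate; single words never are."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    config = config or TokenizerConfig()
    counts: Counter[Tokens] = Counter()
    for doc in collection:
        for sentence in list(doc.title) + list(doc.abstract):
            for run in _runs(sentence, config.stopwords):
                L = len(run)
                for i in range(L - 1):
                    for j in range(i + 2, L + 1):
                        counts[run[i:j]] += 1
    return {
        CandidateString(tokens=toks, corpus_frequency=c, source=HARVESTED)
        for toks, c in counts.items()
        if c >= min_count
    }


def merge_external_lexicon(
    candidates: set[CandidateString],
    lexicon_path: str | Path,
    index: CorpusIndex,
    config: TokenizerConfig | None = None,
) -> set[CandidateString]:
    """Merge an external phrase lexicon into the harvested candidates.

    Lexicon phrases are lowercased and tokenized under the same conventions;
    they are exempt from the minimum-frequency filter and may contain
    stopwords (so e.g. 'activin a' is admissible), but a phrase never seen
    contiguously in the corpus carries no evidence and is dropped (logged).
    A lexicon phrase identical to a harvested candidate keeps its harvested
    entry.
    """
    config = config or TokenizerConfig()
    merged: dict[Tokens, CandidateString] = {c.tokens: c for c in candidates}
    n_added = n_dropped = 0
    for raw in Path(lexicon_path).read_text(encoding="utf-8").splitlines():
        raw = raw.strip()
        if not raw:
            continue
        sentences = tokenize_and_split(raw, config)
        toks = tuple(t for s in sentences for t in s if t != BOUNDARY)
        if len(toks) < 2 or toks in merged:
            continue
        freq = index.occurrence_count(toks)
        if freq == 0:
            n_dropped += 1
            logger.info("lexicon phrase %r absent from corpus; dropped", raw)
            continue
        merged[toks] = CandidateString(tokens=toks, corpus_frequency=freq, source=EXTERNAL)
        n_added += 1
    logger.info("lexicon merge: %d added, %d dropped (zero frequency)", n_added, n_dropped)
    return set(merged.values())
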