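"""Synthetic corpora with planted phrases and known ground truth.

The generator emulates the two structural features the pipeline exploits:

* **Planted contiguity** — designated multi-word phrases are inserted as
  uninterrupted blocks into abstract sentences at a per-sentence rate far
  above what chance adjacency of their words would produce, while
  background words are drawn i.i.d. from a power-law (Zipf-like) unigram
  distribution. Scatter controls insert a phrase's words into the same
  sentence but never adjacently — words that co-occur without forming a
  unit, the situation the stringent contiguous statistic must reject.

* **Title summarization** — a document containing a planted phrase repeats
  it in its title with probability ``title_carry_probability``, so the
  title-based pseudo-relevance labels carry real signal; documents whose
  title features a phrase also add one extra abstract occurrence with
  probability ``carry_boost_probability`` (titles emphasize what abstracts
  dwell on), giving the BM25 rankings something to detect.

Planted-phrase tokens come from a reserved vocabulary block disjoint from
the background so the ground truth is unambiguous. Sentences are built as
lists of atomic elements (a background word, or an entire planted block),
so later insertions can never split a planted phrase; the recorded
occurrence counts therefore rescan cleanly from the emitted text.
Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .corpus_io import Document, DocumentCollection
from .stats_index import Tokens, count_contiguous

_STOPWORD_POOL = ("the", "of", "in", "and", "with", "for", "on", "by", "from")

# a sentence under construction: background/scatter words (str) and planted
# phrase blocks (tuple) that must never be split
_Element = Union[str, Tokens]


@dataclass(frozen=True)
class PlantedPhrase:
    """A token sequence with its per-sentence insertion probability."""

    tokens: Tokens
    insertion_probability: float

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError("planted phrases need >= 2 tokens")
        if not 0.0 <= self.insertion_probability <= 1.0:
            raise ValueError("insertion probability must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters of a simulated titles/abstracts corpus.

    Defaults define the study conditions used throughout the test suite:
    2,000 documents over a 500-word background vocabulary with 50 planted
    two-word phrases inserted in ~1% of abstract sentences (roughly 20x the
    chance adjacency rate of equally frequent independent words), titles
    carrying a contained phrase 60% of the time, and scattered (never
    contiguous) insertions at a fraction of the planted rate.
    """

    n_docs: int = 2000
    sentences_per_abstract: tuple[int, int] = (3, 6)
    sentence_length: tuple[int, int] = (8, 14)
    vocab_size: int = 500
    zipf_exponent: float = 1.1
    n_planted: int = 50
    planted_length: int = 2
    insertion_probability: float = 0.01
    planted_phrases: tuple[PlantedPhrase, ...] | None = None
    n_scatter_controls: int = 10
    scatter_probability: float = 0.002
    title_carry_probability: float = 0.6
    carry_boost_probability: float = 0.5
    stopword_probability: float = 0.08
    comma_probability: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.insertion_probability,
            self.scatter_probability,
            self.title_carry_probability,
            self.carry_boost_probability,
            self.stopword_probability,
            self.comma_probability,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_docs < 1 or self.vocab_size < 2:
            raise ValueError("need at least one document and two background words")

    def resolve_planted(self) -> tuple[PlantedPhrase, ...]:
        """The explicit planted list, or the default reserved-block phrases
        ``p<i>a p<i>b ...`` at the spec's insertion probability."""
        if self.planted_phrases is not None:
            return self.planted_phrases
        suffixes = "abcdefghij"
        return tuple(
            PlantedPhrase(
                tokens=tuple(f"p{i:02d}{suffixes[j]}" for j in range(self.planted_length)),
                insertion_probability=self.insertion_probability,
            )
            for i in range(self.n_planted)
        )

    def resolve_scatter(self) -> tuple[Tokens, ...]:
        """Scatter-control 'phrases' (reserved tokens, never contiguous)."""
        return tuple((f"q{i:02d}a", f"q{i:02d}b") for i in range(self.n_scatter_controls))


@dataclass
class SyntheticGroundTruth:
    """What was planted where, for recovery scoring."""

    planted: set[Tokens]
    scatter_controls: set[Tokens]
    occurrences: dict[str, dict[str, int]]  # doc_id -> phrase text -> contiguous count
    spec: SyntheticSpec | None = field(repr=False, default=None)


def _background_words(rng: np.random.Generator, probs: np.ndarray, k: int) -> list[str]:
    idx = rng.choice(len(probs), size=k, p=probs)
    return [f"w{i:03d}" for i in idx]


def _scatter_into(
    elements: list[_Element], tokens: Tokens, rng: np.random.Generator
) -> list[_Element]:
    """Insert ``tokens`` in order with at least one element between
    consecutive tokens, so they never become adjacent."""
    k = len(tokens)
    if len(elements) < k:
        return elements
    out = list(elements)
    while True:
        positions = sorted(int(x) for x in rng.integers(0, len(out) + 1, size=k))
        if all(positions[i + 1] - positions[i] >= 1 for i in range(k - 1)):
            break
    for tok, pos in zip(reversed(tokens), reversed(positions)):
        out.insert(pos, tok)
    return out


def _render_sentence(
    elements: Sequence[_Element], rng: np.random.Generator, comma_probability: float
) -> str:
    """Flatten blocks and join, attaching an occasional comma after an
    element (never inside a planted block)."""
    parts: list[str] = []
    for i, el in enumerate(elements):
        word = el if isinstance(el, str) else " ".join(el)
        if i < len(elements) - 1 and comma_probability and rng.random() < comma_probability:
            word += ","
        parts.append(word)
    text = " ".join(parts)
    return text[:1].upper() + text[1:] + "."


def generate(spec: SyntheticSpec) -> tuple[DocumentCollection, SyntheticGroundTruth]:
    """Generate a corpus and its ground truth. Deterministic for a fixed
    seed; raises for infeasible specs (phrase longer than the shortest
    sentence)."""
    planted = spec.resolve_planted()
    scatter = spec.resolve_scatter()
    min_len = spec.sentence_length[0]
    for ph in planted:
        if len(ph.tokens) > min_len:
            raise ValueError(f"planted phrase {ph.tokens} longer than the minimum sentence")
    for toks in scatter:
        if len(toks) > min_len:
            raise ValueError(f"scatter control {toks} cannot fit non-contiguously")

    rng = np.random.default_rng(spec.seed)
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()

    docs: list[Document] = []
    occurrences: dict[str, dict[str, int]] = {}

    for d in range(spec.n_docs):
        doc_id = f"{1000000 + d}"
        n_sent = int(
            rng.integers(spec.sentences_per_abstract[0], spec.sentences_per_abstract[1] + 1)
        )
        abstract: list[list[_Element]] = []
        doc_occ: dict[str, int] = {}
        contained: list[PlantedPhrase] = []

        for _ in range(n_sent):
            length = int(rng.integers(spec.sentence_length[0], spec.sentence_length[1] + 1))
            elements: list[_Element] = list(_background_words(rng, probs, length))
            for i in range(len(elements)):
                if rng.random() < spec.stopword_probability:
                    elements[i] = _STOPWORD_POOL[int(rng.integers(len(_STOPWORD_POOL)))]
            for ph in planted:
                if rng.random() < ph.insertion_probability:
                    pos = int(rng.integers(0, len(elements) + 1))
                    elements.insert(pos, ph.tokens)
                    doc_occ[" ".join(ph.tokens)] = doc_occ.get(" ".join(ph.tokens), 0) + 1
                    if ph not in contained:
                        contained.append(ph)
            for ph in planted:
                if rng.random() < spec.scatter_probability:
                    elements = _scatter_into(elements, ph.tokens, rng)
            for toks in scatter:
                if rng.random() < spec.scatter_probability * 5:
                    elements = _scatter_into(elements, toks, rng)
            abstract.append(elements)

        title: list[_Element] = list(
            _background_words(rng, probs, int(rng.integers(3, 7)))
        )
        for ph in contained:
            if rng.random() < spec.title_carry_probability:
                title.append(ph.tokens)
                if rng.random() < spec.carry_boost_probability and abstract:
                    s = int(rng.integers(len(abstract)))
                    pos = int(rng.integers(0, len(abstract[s]) + 1))
                    abstract[s].insert(pos, ph.tokens)
                    doc_occ[" ".join(ph.tokens)] = doc_occ.get(" ".join(ph.tokens), 0) + 1

        raw_abstract = " ".join(
            _render_sentence(s, rng, spec.comma_probability) for s in abstract
        )
        raw_title = _render_sentence(title, rng, 0.0)
        docs.append(Document.from_text(doc_id, raw_title, raw_abstract))
        if doc_occ:
            occurrences[doc_id] = doc_occ

    truth = SyntheticGroundTruth(
        planted={ph.tokens for ph in planted},
        scatter_controls=set(scatter),
        occurrences=occurrences,
        spec=spec,
    )
    return DocumentCollection(documents=docs), truth


def recovery_report(extracted: set[Tokens], truth: SyntheticGroundTruth) -> dict[str, float]:
    """Exact set-based precision/recall/F1 of extracted phrases against the
    planted set (empty extraction: precision 1 by convention, recall 0)."""
    planted = truth.planted
    tp = len(extracted & planted)
    precision = tp / len(extracted) if extracted else 1.0
    recall = tp / len(planted) if planted else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


def rescan_occurrences(
    collection: DocumentCollection, truth: SyntheticGroundTruth
) -> dict[str, dict[str, int]]:
    """Re-count contiguous planted-phrase occurrences in the emitted corpus
    (abstracts), for consistency checks against the recorded ground truth."""
    found: dict[str, dict[str, int]] = {}
    for doc in collection:
        counts: dict[str, int] = {}
        for toks in truth.planted:
            c = sum(count_contiguous(tuple(s), toks) for s in doc.abstract)
            if c:
                counts[" ".join(toks)] = c
        if counts:
            found[doc.doc_id] = counts
    return found


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    """Serialize the ground truth as a JSON sidecar next to a TSV corpus."""
    spec_payload = None
    if truth.spec is not None:
        spec_payload = {
            k: v
            for k, v in asdict(truth.spec).items()
            if k != "planted_phrases" or v is None
        }
    payload = {
        "planted": sorted(" ".join(t) for t in truth.planted),
        "scatter_controls": sorted(" ".join(t) for t in truth.scatter_controls),
        "occurrences": truth.occurrences,
        "spec": spec_payload,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticGroundTruth(
        planted={tuple(p.split()) for p in payload["planted"]},
        scatter_controls={tuple(p.split()) for p in payload["scatter_controls"]},
        occurrences=payload["occurrences"],
        spec=None,
    )
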