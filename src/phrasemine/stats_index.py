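"""Counting statistics over a document collection.

The segmentation stage needs, for any word or contiguous multi-word string,
the number of sentences containing it (N_s, N_t, N'_st and the corpus total
N); the retrieval stage needs document frequencies, in-abstract term
frequencies, abstract lengths and their mean. :class:`CorpusIndex`
precomputes word-level postings at build time and resolves multi-word
(contiguous) statistics lazily with caching, so arbitrary prefixes queried
by the chained test are cheap.

A sentence counts once toward ``sentence_count`` no matter how many times a
unit occurs in it; ``tf`` counts every contiguous occurrence. Contiguity
means the tokens appear adjacently in order with no intervening boundary
marker. Sentence statistics cover titles and abstracts together; document
statistics (df, tf, length) cover abstracts only, since retrieval scores
abstracts and titles serve only as relevance labels.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .corpus_io import BOUNDARY, CorpusError, DocumentCollection, sentence_words

Tokens = tuple[str, ...]


def _as_tokens(unit: str | Sequence[str]) -> Tokens:
    if isinstance(unit, str):
        return tuple(unit.split())
    return tuple(unit)


def count_contiguous(sentence: Sequence[str], tokens: Tokens) -> int:
    """Occurrences of ``tokens`` as an exact consecutive slice of
    ``sentence`` (overlaps allowed). Boundary markers are elements of the
    sentence, so a match can never span one."""
    k = len(tokens)
    if k == 0 or len(sentence) < k:
        return 0
    first = tokens[0]
    n = 0
    for i in range(len(sentence) - k + 1):
        if sentence[i] == first and tuple(sentence[i : i + k]) == tokens:
            n += 1
    return n


class CorpusIndex:
    """All counting statistics the segmentation and retrieval stages query."""

    def __init__(self, collection: DocumentCollection, units: Iterable[Sequence[str]] = ()):
        if len(collection) == 0:
            raise CorpusError("cannot index an empty collection")
        self.collection = collection
        self.doc_ids: list[str] = [d.doc_id for d in collection]

        # sentence-level structures (titles + abstracts)
        self._sentences: list[Tokens] = []
        self._word_sents: dict[str, list[int]] = {}
        # document-level structures (abstracts only)
        self._doc_abstract: list[list[Tokens]] = []
        self._doc_len: dict[str, int] = {}
        self._doc_word_tf: dict[str, Counter] = {}
        self._word_docs: dict[str, set[str]] = {}
        self._title_words: dict[str, set[str]] = {}

        for doc in collection:
            abstract_sents = [tuple(s) for s in doc.abstract]
            self._doc_abstract.append(abstract_sents)
            twords: set[str] = set()
            for sent in doc.title:
                twords.update(sentence_words(sent))
            self._title_words[doc.doc_id] = twords

            tf = Counter()
            for sent in abstract_sents:
                tf.update(w for w in sent if w != BOUNDARY)
            self._doc_word_tf[doc.doc_id] = tf
            self._doc_len[doc.doc_id] = sum(tf.values())
            for w in tf:
                self._word_docs.setdefault(w, set()).add(doc.doc_id)

            for sent in list(doc.title) + list(doc.abstract):
                sid = len(self._sentences)
                self._sentences.append(tuple(sent))
                for w in set(sentence_words(sent)):
                    self._word_sents.setdefault(w, []).append(sid)

        self.N: int = len(self._sentences)
        self.n_docs: int = len(collection)
        total_len = sum(self._doc_len.values())
        self.avgdl: float = total_len / self.n_docs if self.n_docs else 0.0
        if self.avgdl <= 0:
            raise CorpusError("collection has empty abstracts throughout")

        self._abstract_by_id = {
            doc_id: sents for doc_id, sents in zip(self.doc_ids, self._doc_abstract)
        }
        # lazy caches for multi-word units
        self._phrase_sent_count: dict[Tokens, int] = {}
        self._phrase_occurrences: dict[Tokens, int] = {}
        self._phrase_doc_tf: dict[Tokens, dict[str, int]] = {}
        for unit in units:
            toks = _as_tokens(unit)
            self.sentence_count(toks)
            self._phrase_docs(toks)

    # -- sentence statistics ------------------------------------------------

    def sentence_count(self, unit: str | Sequence[str]) -> int:
        """Number of sentences (titles + abstracts) containing the unit; for
        multi-word units the occurrence must be contiguous."""
        toks = _as_tokens(unit)
        if len(toks) == 1:
            return len(self._word_sents.get(toks[0], ()))
        if toks not in self._phrase_sent_count:
            self._scan_phrase_sentences(toks)
        return self._phrase_sent_count[toks]

    def occurrence_count(self, unit: str | Sequence[str]) -> int:
        """Total contiguous occurrences across all sentences (the harvesting
        frequency notion: a sentence may contribute more than once)."""
        toks = _as_tokens(unit)
        if len(toks) == 1:
            return sum(
                count_contiguous(self._sentences[sid], toks)
                for sid in self._word_sents.get(toks[0], ())
            )
        if toks not in self._phrase_occurrences:
            self._scan_phrase_sentences(toks)
        return self._phrase_occurrences[toks]

    def _candidate_sentences(self, toks: Tokens) -> list[int]:
        postings = [self._word_sents.get(w, []) for w in set(toks)]
        return min(postings, key=len)

    def _scan_phrase_sentences(self, toks: Tokens) -> None:
        n_sent = 0
        n_occ = 0
        for sid in self._candidate_sentences(toks):
            c = count_contiguous(self._sentences[sid], toks)
            if c:
                n_sent += 1
                n_occ += c
        self._phrase_sent_count[toks] = n_sent
        self._phrase_occurrences[toks] = n_occ

    # -- document statistics ------------------------------------------------

    def _phrase_docs(self, toks: Tokens) -> dict[str, int]:
        if toks not in self._phrase_doc_tf:
            common: set[str] | None = None
            for w in set(toks):
                docs = self._word_docs.get(w, set())
                common = docs if common is None else common & docs
            tf_map: dict[str, int] = {}
            for doc_id in common or ():
                c = sum(
                    count_contiguous(sent, toks) for sent in self._abstract_by_id[doc_id]
                )
                if c:
                    tf_map[doc_id] = c
            self._phrase_doc_tf[toks] = tf_map
        return self._phrase_doc_tf[toks]

    def doc_freq(self, unit: str | Sequence[str]) -> int:
        """Documents whose abstract contains the unit (contiguously, for
        multi-word units)."""
        toks = _as_tokens(unit)
        if len(toks) == 1:
            return len(self._word_docs.get(toks[0], ()))
        return len(self._phrase_docs(toks))

    def tf(self, doc_id: str, unit: str | Sequence[str]) -> int:
        """Occurrences of the unit in the document's abstract (contiguous
        occurrences for multi-word units, overlaps allowed)."""
        toks = _as_tokens(unit)
        if len(toks) == 1:
            return self._doc_word_tf[doc_id][toks[0]]
        return self._phrase_docs(toks).get(doc_id, 0)

    def docs_containing_phrase(self, unit: str | Sequence[str]) -> list[str]:
        """Sorted ids of documents whose abstract contains the unit
        contiguously."""
        toks = _as_tokens(unit)
        if len(toks) == 1:
            return sorted(self._word_docs.get(toks[0], ()))
        return sorted(self._phrase_docs(toks))

    def abstract_len(self, doc_id: str) -> int:
        return self._doc_len[doc_id]

    def title_contains_all(self, doc_id: str, words: Iterable[str]) -> bool:
        return set(words) <= self._title_words[doc_id]

    def abstract_contains_all(self, doc_id: str, words: Iterable[str]) -> bool:
        return all(self._doc_word_tf[doc_id][w] > 0 for w in set(words))

    def docs_with_all_words(self, words: Iterable[str]) -> list[str]:
        """Sorted ids of documents whose abstract contains every word (in any
        positions) — the candidate pool A∪T for a phrase-query."""
        common: set[str] | None = None
        for w in set(words):
            docs = self._word_docs.get(w, set())
            common = docs if common is None else common & docs
            if not common:
                return []
        return sorted(common or ())


def build_index(
    collection: DocumentCollection, units: Iterable[Sequence[str]] = ()
) -> CorpusIndex:
    """Build a :class:`CorpusIndex`, optionally pre-warming the caches for a
    set of tracked multi-word strings."""
    return CorpusIndex(collection, units=units)
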