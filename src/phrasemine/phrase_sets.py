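"""Final phrase-set assembly and the released output file formats.

Four companion files are written for a selected phrase set ``<stem>``:

``<stem>.txt``
    one phrase per line.
``<stem>.group``
    phrase, then every strict contiguous sub-phrase (length >= 2) that is
    itself in the set, tab-separated.
``<stem>.pmid``
    phrase, then the sorted ids of documents containing it contiguously,
    tab-separated.
``<stem>.sco``
    vertical-bar-separated: phrase | comma-separated chained-test p-values
    in chain order | the two average precisions, word-based then
    phrase-based, comma-separated.

Numbers are printed with 6 significant digits; output is deterministic
(byte-identical for identical inputs). An optional part-of-speech hook can
produce a ``.pos`` analog, but no tagger is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .retrieval_filter import PhraseEvaluation
from .segmentation import SegmentationTrace
from .stats_index import CorpusIndex, Tokens

DEFAULT_STEM = "all_dictionary"

#: Signature of the pluggable POS hook: (phrase tokens, example sentences)
#: -> one tag per token.
PosTagger = Callable[[Tokens, Sequence[Sequence[str]]], Sequence[str]]


def _fmt(x: float) -> str:
    return format(x, ".6g")


@dataclass
class PhraseSetEntry:
    """One selected phrase with its segmentation trace, retrieval evidence,
    document list and in-set sub-phrases."""

    trace: SegmentationTrace
    evaluation: PhraseEvaluation
    pmids: list[str]
    subphrases: list[Tokens]

    @property
    def tokens(self) -> Tokens:
        return self.trace.candidate.tokens

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def group_subphrases(phrase_set: Iterable[Tokens]) -> dict[Tokens, list[Tokens]]:
    """For each phrase, list the strict contiguous token subsequences of
    length >= 2 that are themselves members of the set, ordered by start
    position then length."""
    members = set(phrase_set)
    out: dict[Tokens, list[Tokens]] = {}
    for phrase in members:
        L = len(phrase)
        subs = [
            phrase[i:j]
            for i in range(L)
            for j in range(i + 2, L + 1)
            if (j - i) < L and phrase[i:j] in members
        ]
        out[phrase] = subs
    return out


def build_entries(
    traces: Mapping[Tokens, SegmentationTrace],
    evaluations: Mapping[Tokens, PhraseEvaluation],
    index: CorpusIndex,
) -> list[PhraseSetEntry]:
    """Assemble entries for the selected phrases (those whose evaluation
    passed all criteria), sorted lexicographically by phrase."""
    selected = sorted(t for t, ev in evaluations.items() if ev.selected)
    groups = group_subphrases(selected)
    entries = []
    for toks in selected:
        pmids = index.docs_containing_phrase(toks)
        entries.append(
            PhraseSetEntry(
                trace=traces[toks],
                evaluation=evaluations[toks],
                pmids=pmids,
                subphrases=groups[toks],
            )
        )
    return entries


def write_outputs(
    entries: Sequence[PhraseSetEntry],
    out_dir: str | Path,
    stem: str = DEFAULT_STEM,
    pos_tagger: PosTagger | None = None,
    example_sentences: Mapping[Tokens, Sequence[Sequence[str]]] | None = None,
) -> dict[str, Path]:
    """Write the four companion files (plus ``.pos`` if a tagger is given).
    Returns the mapping of extension -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {ext: out / f"{stem}.{ext}" for ext in ("txt", "group", "pmid", "sco")}

    entries = sorted(entries, key=lambda e: e.tokens)
    with open(paths["txt"], "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(e.text + "\n")
    with open(paths["group"], "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write("\t".join([e.text] + [" ".join(s) for s in e.subphrases]) + "\n")
    with open(paths["pmid"], "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write("\t".join([e.text] + list(e.pmids)) + "\n")
    with open(paths["sco"], "w", encoding="utf-8") as fh:
        for e in entries:
            pvals = ",".join(_fmt(p) for p in e.trace.step_pvalues)
            aps = ",".join(_fmt(a) for a in (e.evaluation.ap_word, e.evaluation.ap_phrase))
            fh.write(f"{e.text}|{pvals}|{aps}\n")

    if pos_tagger is not None:
        pos_path = out / f"{stem}.pos"
        with open(pos_path, "w", encoding="utf-8") as fh:
            for e in entries:
                examples = (example_sentences or {}).get(e.tokens, ())
                tags = pos_tagger(e.tokens, examples)
                fh.write("\t".join([e.text, " ".join(tags)]) + "\n")
        paths["pos"] = pos_path
    return paths


def read_outputs(out_dir: str | Path, stem: str = DEFAULT_STEM) -> dict[str, dict]:
    """Read the four companion files back into plain dictionaries keyed by
    phrase text (for round-trip checks and downstream consumers)."""
    out = Path(out_dir)
    phrases = [
        line.rstrip("\n")
        for line in (out / f"{stem}.txt").read_text(encoding="utf-8").splitlines()
    ]
    groups: dict[str, list[str]] = {}
    for line in (out / f"{stem}.group").read_text(encoding="utf-8").splitlines():
        cols = line.split("\t")
        groups[cols[0]] = cols[1:]
    pmids: dict[str, list[str]] = {}
    for line in (out / f"{stem}.pmid").read_text(encoding="utf-8").splitlines():
        cols = line.split("\t")
        pmids[cols[0]] = cols[1:]
    scores: dict[str, dict] = {}
    for line in (out / f"{stem}.sco").read_text(encoding="utf-8").splitlines():
        phrase, pvals, aps = line.split("|")
        ap_word, ap_phrase = (float(x) for x in aps.split(","))
        scores[phrase] = {
            "p_values": [float(x) for x in pvals.split(",")] if pvals else [],
            "ap_word": ap_word,
            "ap_phrase": ap_phrase,
        }
    return {"phrases": phrases, "groups": groups, "pmids": pmids, "scores": scores}
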