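"""Corpus reading, normalization, sentence splitting and tokenization.

Documents are records with an identifier, a title and an abstract. Text is
lowercased and split into sentences; within a sentence, tokens are separated
by whitespace and boundary punctuation, while hyphens and apostrophes are
kept inside tokens (so ``3'-utr`` and ``zinc-finger`` are single tokens).
Boundary punctuation positions are preserved in the token stream as the
marker :data:`BOUNDARY`, because candidate phrases may never span them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

#: Marker inserted where boundary punctuation occurred. Real tokens can never
#: equal it (tokens contain at least one alphanumeric character).
BOUNDARY = "|"

#: The ~130-word PubMed/NLM stopword list, used both as phrase boundaries
#: during candidate harvesting and (optionally) elsewhere. Overridable via
#: :func:`load_stopwords`.
DEFAULT_STOPWORDS = frozenset(
    """
    a about again all almost also although always among an and another any
    are as at be because been before being between both but by can could did
    do does done due during each either enough especially etc for found from
    further had has have having here how however i if in into is it its
    itself just kg km made mainly make may mg might ml mm most mostly must
    nearly neither no nor obtained of often on our overall perhaps pmid
    quite rather really regarding seem seen several should show showed shown
    shows significantly since so some such than that the their theirs them
    then there therefore these they this those through thus to upon various
    very was we were what when which while with within without would
    """.split()
)

DEFAULT_BOUNDARY_PUNCTUATION = frozenset(".,;:!?()[]{}<>\"/\\|=+*&%$#@~`^_…“”‘’")

_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")


class CorpusError(ValueError):
    """Raised for malformed corpora (bad XML/TSV, duplicate ids, empty input)."""


@dataclass(frozen=True)
class TokenizerConfig:
    """Delimiter conventions for tokenization and candidate harvesting.

    ``stopwords`` bound candidate phrases (they are still tokens);
    ``boundary_punctuation`` characters delimit tokens and are recorded as
    :data:`BOUNDARY` markers; ``intra_token_characters`` are never treated as
    delimiters and must include the hyphen and the apostrophe.
    """

    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    boundary_punctuation: frozenset[str] = DEFAULT_BOUNDARY_PUNCTUATION
    intra_token_characters: frozenset[str] = frozenset("-'’")

    def __post_init__(self) -> None:
        if "-" not in self.intra_token_characters or "'" not in self.intra_token_characters:
            raise ValueError("hyphen and apostrophe must be intra-token characters")
        overlap = self.boundary_punctuation & self.intra_token_characters
        if overlap - {"’"}:
            raise ValueError(f"characters both boundary and intra-token: {overlap}")

    def __hash__(self) -> int:  # frozensets of strs hash fine
        return hash((self.stopwords, self.boundary_punctuation, self.intra_token_characters))


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file (one lowercase word per line, blank lines ignored)."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip().lower()
        if w:
            words.append(w)
    return frozenset(words)


def split_sentences(text: str) -> list[str]:
    """Split raw text at sentence-final punctuation followed by whitespace
    and an uppercase letter or digit. Deliberately simple; the co-occurrence
    statistics are robust to modest splitting noise."""
    text = text.strip()
    if not text:
        return []
    return [s for s in _SENTENCE_SPLIT_RE.split(text) if s.strip()]


def _tokenize_sentence(sentence: str, config: TokenizerConfig) -> list[str]:
    """Lowercase and tokenize one sentence, inserting BOUNDARY markers where
    boundary punctuation occurred. Runs of boundaries collapse to a single
    marker; leading/trailing markers are trimmed."""
    out: list[str] = []
    cur: list[str] = []
    pending_boundary = False

    def flush() -> None:
        nonlocal pending_boundary
        if cur:
            tok = "".join(cur)
            # a token must contain at least one alphanumeric character
            if any(c.isalnum() for c in tok):
                if pending_boundary and out:
                    out.append(BOUNDARY)
                out.append(tok)
                pending_boundary = False
            cur.clear()

    for ch in sentence.lower():
        if ch.isspace():
            flush()
        elif ch in config.boundary_punctuation and ch not in config.intra_token_characters:
            flush()
            pending_boundary = True
        else:
            cur.append(ch)
    flush()
    return out


def tokenize_and_split(text: str, config: TokenizerConfig | None = None) -> list[list[str]]:
    """Tokenize raw text into sentences of lowercase tokens with BOUNDARY
    markers. Empty text yields an empty list."""
    config = config or TokenizerConfig()
    return [toks for s in split_sentences(text) if (toks := _tokenize_sentence(s, config))]


def sentence_words(sentence: Iterable[str]) -> list[str]:
    """Drop BOUNDARY markers, leaving only real tokens."""
    return [t for t in sentence if t != BOUNDARY]


@dataclass
class Document:
    """One corpus record: an id plus tokenized title and abstract sentences."""

    doc_id: str
    title: list[list[str]]
    abstract: list[list[str]]
    raw_title: str = ""
    raw_abstract: str = ""

    @classmethod
    def from_text(
        cls, doc_id: str, title: str, abstract: str, config: TokenizerConfig | None = None
    ) -> "Document":
        return cls(
            doc_id=doc_id,
            title=tokenize_and_split(title, config),
            abstract=tokenize_and_split(abstract, config),
            raw_title=title,
            raw_abstract=abstract,
        )


@dataclass
class DocumentCollection:
    """An ordered collection of documents with unique ids, plus a count of
    input records skipped for lacking an abstract."""

    documents: list[Document] = field(default_factory=list)
    skipped: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if not doc.doc_id:
                raise CorpusError("empty document id")
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate document id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]


def read_medline_xml(path: str | Path, config: TokenizerConfig | None = None) -> DocumentCollection:
    """Read a PubMed/MEDLINE XML file into a :class:`DocumentCollection`.

    One document per article record that has both a title and a non-empty
    abstract; abstract-less records are skipped and counted in
    ``collection.skipped``. Malformed XML raises :class:`CorpusError` naming
    the parser position; zero usable records is an error.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc

    docs: list[Document] = []
    skipped = 0
    articles = tree.findall(".//PubmedArticle")
    if not articles:
        articles = tree.findall(".//Article")  # tolerate a bare <Article> dialect
    for art in articles:
        pmid = art.findtext(".//PMID") or art.get("pmid") or ""
        title_node = art.find(".//ArticleTitle")
        title = "".join(title_node.itertext()) if title_node is not None else ""
        abstract_parts = [
            "".join(node.itertext()) for node in art.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(p.strip() for p in abstract_parts if p and p.strip())
        if not abstract:
            skipped += 1
            continue
        docs.append(Document.from_text(pmid.strip(), title.strip(), abstract, config))
    if not docs:
        raise CorpusError(f"no usable records (records skipped: {skipped}) in {path}")
    return DocumentCollection(documents=docs, skipped=skipped)


def read_tsv_corpus(path: str | Path, config: TokenizerConfig | None = None) -> DocumentCollection:
    """Read the plain TSV dialect ``id<TAB>title<TAB>abstract`` (UTF-8, no
    header). Wrong column counts raise :class:`CorpusError` with the line
    number; records with an empty abstract are skipped and counted."""
    docs: list[Document] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            doc_id, title, abstract = parts
            if not abstract.strip():
                skipped += 1
                continue
            docs.append(Document.from_text(doc_id.strip(), title.strip(), abstract.strip(), config))
    if not docs:
        raise CorpusError(f"no usable records in {path}")
    return DocumentCollection(documents=docs, skipped=skipped)


def write_tsv_corpus(collection: DocumentCollection, path: str | Path) -> None:
    """Write a collection back to the TSV dialect (raw title/abstract text)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in collection:
            for fieldval in (doc.raw_title, doc.raw_abstract):
                if "\t" in fieldval:
                    raise CorpusError(f"embedded tab in document {doc.doc_id!r}")
            fh.write(f"{doc.doc_id}\t{doc.raw_title}\t{doc.raw_abstract}\n")
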