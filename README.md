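# phrasemine

Biomedical text is full of multi-word concepts — *zinc finger protein*,
*familial mediterranean fever* — that behave as single units in search and
comprehension, yet most retrieval systems treat queries as bags of words.
`phrasemine` mines such **coherent phrases** from any corpus of document
titles and abstracts (MEDLINE/PubMed XML or a plain TSV dialect), for
people building literature-search, query-segmentation or text-mining
systems who need a data-driven phrase lexicon rather than a curated
vocabulary.

## The method

The pipeline is unsupervised and has two stages.

**1. Chained hypergeometric segmentation.** Candidate strings are all
multi-word text strings bounded by punctuation or stopwords that occur at
least `min_count` (default 5) times, optionally merged with an external
lexicon (one phrase per line; those may contain stopwords, e.g.
*activin a*). For two units with sentence counts N<sub>s</sub> and
N<sub>t</sub> out of N corpus sentences, the number of sentences Y
containing both under independence is hypergeometric:

```
P(Y = y) = C(N_t, y) · C(N − N_t, N_s − y) / C(N, N_s)
```

The observed statistic N′<sub>st</sub> counts only sentences where the two
units are **adjacent as a phrase**, and the p-value is the upper tail
Σ P(Y = y) for y = N′<sub>st</sub> … min(N<sub>s</sub>, N<sub>t</sub>) —
a deliberately stringent substitution, since N′<sub>st</sub> ≤ N<sub>st</sub>.
A k-word candidate is tested left to right (chunk w₁…wᵢ against word
wᵢ₊₁); it is a coherent segment iff every step's p-value is ≤ 0.01, with a
Benjamini–Hochberg step-up correction applied within each candidate's
family of tests.

**2. BM25 retrieval filtering.** Each coherent segment becomes a query.
Every document whose abstract contains all its words forms the pool A∪T;
a document is a pseudo-relevant positive (set T) when its **title** also
contains all the words, else a negative (set A). Abstracts are ranked by
Okapi BM25 twice — scoring the individual words, and scoring the phrase as
one multi-word term whose tf/df count only contiguous occurrences — and
each ranking is summarized by average precision (AP). A phrase is kept iff

1. |T| ≥ 5,
2. phrase-based AP > word-based AP,
3. phrase-based AP > the expected AP of a random ranking of the pool,
4. word-based AP > 0.01.

Phrases whose relative AP improvement `(AP_phrase − AP_word)/AP_word` is at
least 10 % form the high-improvement subset (`small_dictionary.txt`).

A fully seeded synthetic-corpus generator (planted contiguous phrases,
scattered negative controls, titles that summarize abstracts) provides
ground truth for testing every stage; see `docs/methods.md`.

## Worked example

```
$ phrasemine simulate --out-dir demo --seed 3 --n-docs 250 --n-planted 8
wrote 250 documents to demo/corpus.tsv
$ phrasemine run demo/corpus.tsv --out-dir demo/out --seed 3
candidates=323 accepted=8 selected=4 small=0
```

323 candidate strings were harvested from the 1,388 sentences; the chained
hypergeometric test accepted exactly the 8 planted phrases (no background
bigram is significant under the contiguity-stringent test), and at this
small corpus size 4 of the 8 also pass all four retrieval criteria. The
`.sco` file records, per selected phrase, its chain of step p-values and
the two APs (word-based, then phrase-based):

```
$ head -2 demo/out/all_dictionary.sco
p02a p02b|3.58901e-51|0.755824,0.812629
p03a p03b|9.48958e-48|0.765873,0.780627
```

e.g. *p02a p02b* co-occurs contiguously far beyond chance (p ≈ 4·10⁻⁵¹)
and ranking it as a unit raises AP from 0.756 to 0.813. The other outputs
are `all_dictionary.txt` (the phrase list), `.group` (phrases nested inside
each phrase), `.pmid` (documents containing each phrase contiguously), and
`report.json` (per-stage counts and the full configuration).

The same pipeline runs on real corpora:

```
phrasemine run pubmed_batch.xml --out-dir out --lexicon umls_phrases.txt
```

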