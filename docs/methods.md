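# Methods

## Model and procedure

`phrasemine` identifies multi-word strings that (a) occur contiguously far
more often than chance given their parts' frequencies and (b) measurably
improve retrieval when treated as a single query term.

### Co-occurrence model

Sentences are the co-occurrence unit. For units u₁, u₂ present in
N_s and N_t of the N corpus sentences, the count Y of sentences containing
both is, under independence, hypergeometric with parameters (N, N_s, N_t).
The test statistic substitutes the stricter contiguous count N′_st
(sentences containing "u₁ u₂" adjacently, with no intervening boundary
punctuation) for the plain co-membership count, and the p-value is the
upper tail P(Y ≥ N′_st). Because N′_st ≤ N_st this can only lower the
observed count relative to the co-membership null, which makes the test
conservative for frequent word pairs: words that co-occur often but rarely
adjacently produce p ≈ 1. Sentences are counted from titles and abstracts
together (titles are ordinary text for co-occurrence purposes; the paper
trail of a phrase is its behaviour anywhere in the record).

Multi-word candidates are tested by chaining: step i tests the contiguous
chunk w₁…wᵢ (N_s = its contiguous-sentence count) against the single word
wᵢ₊₁ (N_t = its word sentence count), with N′_st the contiguous count of
the chunk extended by that word. Using the contiguous chunk count — rather
than the count of sentences containing the chunk's words in any order —
keeps the stringent-contiguity philosophy consistent at every step. All
step p-values are computed and recorded even past a failing step, so the
`.sco` output always carries the full chain.

Each candidate entails k−1 tests, so a Benjamini–Hochberg step-up
correction is applied *within each candidate's family* (not corpus-wide):
sort the step p-values, reject ranks ≤ the largest k with p₍ₖ₎ ≤ k·q/m,
and eliminate the candidate unless every step is rejected. The per-family
scope follows from accepting a fixed error rate across candidates rather
than controlling a global FDR over millions of tests. Boundary comparisons
are inclusive (a p-value exactly at the threshold passes) for
bit-reproducibility; the step-up is implemented directly so this
convention is explicit, and the test suite cross-checks it against
statsmodels' `fdr_bh` on random families.

### Retrieval filter

A surviving phrase is treated as a query. The judged pool is every
document whose abstract contains all the phrase's words in any positions;
the label is positive exactly when the title also contains all the words.
Titles containing only some of the words are negatives — a conservative
choice that makes the measured average precision a lower bound. BM25
(k1 = 1.2, b = 0.75, the standard Okapi constants; exposed in config)
scores abstracts only, in two modes: summing per-word contributions, or
treating the phrase as one term whose tf counts contiguous abstract
occurrences and whose df counts documents containing it contiguously. idf
uses ln((D − df + 0.5)/(df + 0.5)) with a configurable floor (default 0,
so terms in more than half the collection contribute nothing rather than
negatively). df, avgdl and document lengths are computed over the whole
collection, mirroring a real search index. Rankings sort by descending
score with ties broken by ascending document id, making average precision
deterministic.

The four selection criteria (pool with ≥ 5 positives; phrase-AP strictly
above word-AP; phrase-AP above the random-ranking baseline; word-AP above
0.01) are evaluated per phrase, and the high-improvement subset keeps
phrases with relative improvement ≥ 10 %. The random baseline is the
expected AP of a uniformly random permutation of the pool: exact (by
enumerating the C(n_total, n_pos) equally likely placements of the
positive ranks) for pools of ≤ 8 documents, otherwise a seeded Monte-Carlo
mean over 1,000 permutations (configurable). The full ranked pool is used
— no top-k truncation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_count` | 5 | minimum contiguous occurrences for a harvested candidate |
| `alpha` | 0.01 | per-step p-value threshold of the chained test |
| `bh_q` | 0.01 | FDR level of the per-candidate BH correction |
| `k1`, `b`, `idf_floor` | 1.2, 0.75, 0 | Okapi BM25 constants |
| `min_pos` | 5 | minimum \|T\| (criterion 1) |
| `ap_word_floor` | 0.01 | minimum word-based AP (criterion 4) |
| `min_improvement` | 0 / 0.10 | relative-improvement bound (full / small set) |
| `baseline_reps` | 1000 | Monte-Carlo permutations for the random baseline |

Tokenization lowercases everything (published phrase sets of this kind
contain lowercase entries such as 'activin a', and case-insensitive
matching maximizes counts); hyphens and apostrophes are never delimiters;
numerals and single characters are legal tokens. Sentences split at
terminal punctuation followed by whitespace and an uppercase letter or
digit — a deliberately simple rule, since the sentence-level statistics
are robust to modest splitting noise. Titles are therefore almost always a
single sentence. The default stopword list is the ~130-word PubMed/NLM
list embedded in `corpus_io` and overridable by file.

## Synthetic corpus

The generator emulates exactly the structure the method exploits, and no
more:

* background tokens drawn i.i.d. from a power-law unigram distribution
  (exponent 1.1) over a configurable vocabulary — natural-language
  frequency skew without grammar (a uniform background would make the
  hypergeometric test unrealistically easy);
* planted phrases from a reserved token block, inserted as atomic
  contiguous blocks in ~1 % of abstract sentences (defaults: 2,000
  documents, 50 two-word phrases) — roughly 20× the chance adjacency rate
  of equally frequent independent words;
* scattered insertions of the same words with at least one token between
  them, plus dedicated scatter-only control "phrases": co-occurrence
  without unit-hood, which the contiguity-stringent test must reject and
  which create the documents where phrase-based ranking genuinely beats
  word-based ranking;
* titles that summarize: a document containing a planted phrase carries it
  in the title with probability 0.6, and title-carrying documents add one
  extra abstract occurrence with probability 0.5. Without some
  title–abstract association beyond the label itself, both scorers rank
  the pool near-identically and the directional comparisons would have no
  signal to find.

Planted phrases default to bigrams: nested sub-runs of longer planted
phrases are themselves genuinely coherent units, which would make exact
set-based recovery scoring ambiguous; longer phrases are available through
`planted_phrases` for targeted tests. Sentences are built from atomic
elements so no later insertion can split a planted block; the recorded
ground-truth occurrence counts therefore rescan exactly from the emitted
text.

What passing on this corpus does **not** show: robustness to real
morphology, synonymy, abbreviation variants, sentence-splitting errors on
real prose, or the candidate-volume regime of a full bibliographic
database (tens of millions of strings). The generator's scale — about
11,000 sentences — was chosen so the full pipeline runs in seconds; all
statistics scale with counts, not with corpus identity.

## Numerical choices

* Hypergeometric pmf and upper tail are evaluated with `scipy.stats.hypergeom`
  (Boost-backed, accurate in deep tails); the test suite checks the tail
  against exact rational (Fraction) summation at relative error ≤ 1e−10.
* N′_st = 0 yields p = 1 by definition (the whole support is summed);
  a candidate whose full string never occurs contiguously is discarded
  outright.
* All threshold comparisons are inclusive (≤ for p-values, ≥ for counts
  and improvements), stated for reproducibility.
* AP tie-breaking is part of the contract: descending score, then
  ascending document id.
* Degenerate judged sets (no positives) short-circuit: APs are undefined
  (reported as null) and all criteria fail.
* Output numbers are printed with 6 significant digits; all files are
  UTF-8, newline-terminated, and byte-identical across runs with the same
  config and seed.

## Known limitations

* The `.pos` companion file (part-of-speech tags) is supported only
  through a pluggable tagger hook; no tagger is bundled.
* External lexicons are flat phrase lists; parsing UMLS distribution
  files is out of scope.
* The retrieval filter assumes exact word/phrase matching — no synonym
  expansion, by design.
* Harvesting all contiguous sub-runs is quadratic in run length; extremely
  long boundary-free runs (unrealistic in natural text) would be slow.
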