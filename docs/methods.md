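# Methods

## The retrieval model

`necrotext` implements single-word, term-based retrieval over multi-field
clinical free text with rule-based negation detection. A record is
retrieved for a query iff at least one searchable narrative field contains
at least one occurrence of a query term that is not negated. An occurrence
is negated iff a word from the negator lexicon lies inside the same
*phrase window*: the token span extending from the term to the first
phrase-boundary punctuation mark on each side, capped at `window_size`
word tokens per side.

Assumptions this model makes, and that its evaluation machinery is built
to probe:

- findings are expressed by single words, so multi-word descriptors
  ("low body condition") are invisible unless one of their words is
  selected; n-gram queries are deliberately out of scope;
- negation scope is purely punctuation- and distance-bounded, with no
  syntactic analysis — comma placement and slashes change verdicts;
- term selection is a human act; the machine only ranks candidates.

## Tokenization and window rules

Words are maximal `[A-Za-z0-9]+` runs; every other non-space character is
its own punctuation token, and the newline is an explicit token so it can
end phrases. Matching is case-insensitive, whole-token, with no stemming.
Design choices that were genuinely open, and how they were fixed:

- **"Ten-word window" reads as ten words on each side** of the term, not
  ten in total. The symmetric reading is the only one consistent with a
  bound applied "before and after" the term, and it is configurable
  (`SearchQuery.window_size`).
- **Window size counts word tokens only**; non-boundary punctuation (a
  hyphen, an apostrophe) passes through without consuming budget.
- **Phrase boundaries** default to `. , ; : ! ? / ( )` and newline. The
  slash must be a boundary to reproduce the documented
  escape-from-negation behaviour; the hyphen must not be one, so that
  hyphenated compounds ("post-mortem") split into searchable parts
  without breaking the phrase.
- **Negator lexicon** defaults to `no, not, never, neither, nor, without,
  absent` and is user-extensible; every CLI run logs the effective
  lexicon. A token that is simultaneously a query term and a negator
  counts as a match and never negates itself.
- **Searchable fields** default to *all* narrative fields, history
  included — history-only mentions are a documented false-positive
  mechanism, and excluding history is a supported schema configuration
  rather than the default.

## TF-IDF candidate generation

Default score `tf(t, d) · ln(N / df(t))`, unsmoothed and stop-list-free.
The verbal description this component follows ("a ratio of how frequently
each word is found in an individual record to how frequently it is seen in
all the uploaded records") is ambiguous between classic TF-IDF and a raw
frequency ratio, so a second variant,
`tf(t, d) / total corpus occurrences of t`, ships behind
`variant="freq_ratio"`; neither is claimed bit-identical to any particular
register UI. Per-record ranking breaks ties by (score desc, tf desc, term
asc), which makes top-N lists *nested* in N — the property the top-N sweep
semantics relies on — and makes candidate lists independent of record
order. In a single-record corpus every idf is ln(1) = 0 and the tie-break
degrades to plain tf ranking, so the candidate list stays useful.

## Evaluation conventions

- TP/FP/FN only; TN and specificity are never computed.
- recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = harmonic mean.
  Zero-denominator cases are *flagged* (`None`) rather than reported as 0:
  recall is undefined when the reference set is empty, precision when
  nothing was retrieved; F1 is 0 whenever TP = 0. Aggregates skip
  undefined values.
- Across-tester aggregation uses the arithmetic mean and the sample
  (n−1) standard deviation — testers are treated as a sample of possible
  users; a single tester reports sd as not available.
- Misclassification summaries report percentages as 100·x/n rounded
  half-up to one decimal, computed in exact decimal arithmetic.
- One cause code per misclassified (accession, direction) pair, enforced
  as an invariant; only *propagation* of codes by accession match is
  automated, never their assignment from text.
- Three-letter word stems are the distinct leading trigrams of the
  lowercased terms (shorter terms contribute their whole form); the stem
  count of a term set is the package's measure of vocabulary breadth.

## Synthetic corpus generator

The generator emulates the structure that matters to this pipeline, not
linguistic realism: multi-field records assembled from a fixed template
bank with slot filling, so every planted mention's field, surface form and
engine-effective negation status is recorded in a log from which a test
oracle predicts retrieval outcomes exactly.

Default study conditions (chosen once, as a plausible register extract;
all configurable):

- **Findings** — four profiles spanning the breadth spectrum: `Oil`
  (narrow: oil/oiled/oiling, one stem, prevalence 0.15, usage weights
  0.6/0.25/0.15), `Trauma` (broad: six distinct-stem terms, 0.30),
  `DipStom` (narrow but typo-prone: stomatitis/diphtheritic plus two
  misspelled variants, 0.25), `Starve` (broad: seven terms, many stems,
  0.30). Vocabularies must be disjoint across profiles so the planted log
  fully explains every engine match.
- **Trap rates** (per record and finding) — negated mention in a negative
  record 0.10; missing-comma negation leak in a positive record 0.02;
  slash-joined escape in a negative record 0.02; history-only mention
  0.03; misspelled-variant positive 0.05.
- One `random.Random(seed)` stream per corpus; identical arguments give
  byte-identical corpora and logs; the seed is written into the log.

What the generator does *not* emulate — and hence what green tests do not
show about real data: realistic prose variability, multi-word finding
descriptors, inter-annotator disagreement in the reference sets,
co-occurring findings in one sentence, and human search-term selection
behaviour. Passing end-to-end tests demonstrate that the engine implements
its stated rules exactly, not that those rules suffice on register text.

## Numerical and degenerate-input choices

- Percentages: exact `Decimal` arithmetic, ROUND_HALF_UP to 1 decimal.
- Scores: IEEE doubles; candidate ranking uses the deterministic
  tie-break above, so float ties cannot reorder runs.
- Empty corpus: scoring and candidate generation raise a usage error;
  an empty CSV reads as an empty corpus without error.
- Empty effective query in a sweep condition: reported with TP = 0 and
  flagged, not dropped.
- Problem sizes used by the shipped checks: 500-record corpora for
  end-to-end recovery and the acceptance script, 1,000+ random sentences
  for the negation-oracle equivalence suite, three seeds × 250 records
  for the breadth-effect comparison.

## Known limitations

- Single-word terms only; negation scope is syntax-blind by design.
- The TF-IDF formula of any particular production register UI is not
  printed anywhere authoritative; two documented variants are provided.
- The misclassification taxonomy is annotated by humans; the package only
  propagates and summarises codes.
- The generator's trap templates are stylised single-sentence mechanisms;
  real grammatical traps are more varied.
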