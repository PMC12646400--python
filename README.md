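# necrotext

Negation-aware free-text retrieval and evaluation for wildlife necropsy
report corpora.

Wildlife pathology registers hold decades of free-text necropsy reports —
a rich passive-surveillance resource for conservation and One Health work
that is usually mined by close reading. `necrotext` implements the
term-based retrieval workflow such registers can use instead, together
with everything needed to *evaluate* it: a user uploads a CSV of records,
picks search terms from a TF-IDF-derived candidate list, and retrieves the
unique records that mention a term **without a negator in the same
phrase**. The package is aimed at wildlife-health data scientists and
veterinary epidemiologists who want to study (or reuse) this class of
rule-based pipeline without access to a live register.

## The method

**Candidate terms.** Every word *t* of record *d* in a corpus of *N*
records is scored

```
tfidf(t, d) = tf(t, d) · ln(N / df(t))
```

with `tf` the within-record count and `df` the number of records
containing *t*. Each record contributes its top-N words (N = 40 by
default) to the selectable candidate list; a partial-word lookup helps the
user find terms in it.

**Negation-aware search.** A record is retrieved for a query iff some
searchable field contains a query term with no negator word (`no`, `not`,
`never`, …) inside the same *phrase* — the span bounded by the first
punctuation mark on each side of the term, capped at ten word tokens per
side. Punctuation therefore drives the classic failure modes, which the
package reproduces exactly: a stray comma breaks a genuine negation
("No, signs of oiling" *is* retrieved for `oiling`), a slash ends the
phrase ("no signs of trauma/ predation" is retrieved for `predation`),
and a missing comma lets a negator leak into a positive clause
("Stomatitis not found but multiple lacerations present on the body" is
*not* retrieved for `lacerations`).

**Evaluation.** Retrieved accession sets are scored against manually
curated reference sets as TP/FP/FN, then recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = their harmonic mean. Misclassified records
carry one of six cause codes (R record structure, S search-term use,
I interpretation, G grammar, T typography, U unknown); codes propagate
from an annotated dataset to further testers' FP/FN sets by accession
match, and summaries report per-code percentages. A top-N sweep re-runs a
recorded query under candidate lists restricted to top 40/20/10/5.

**Synthetic corpora.** A seeded generator plants findings with narrow
(single-stem) or broad (many-synonym) vocabularies into templated
necropsy prose, along with negations and the trap mechanisms above, and
emits exact ground truth — so the whole pipeline is testable end-to-end
without register data.

## Worked example

```
necrotext simulate --n 120 --seed 42 --out corpus.csv --log planted.csv
necrotext search --corpus corpus.csv --terms oil,oiled,oiling --out hits.csv
necrotext evaluate --hits hits.csv --reference ref_Oil.csv --out metrics.json
```

prints:

```
wrote 120 records to corpus.csv (seed=42)
19 unique records retrieved
{"tp": 16, "fp": 3, "fn": 0, "recall": 1.0, "precision": 0.8421052631578947, "f1": 0.9142857142857143}
```

All 16 planted oiling-positive records were retrieved (recall 1.0); the 3
false positives are trap records — history-only oil-spill mentions and
slash-joined terms that escaped negation — so precision is 0.84 and the F1
score 0.91. The same objects are available from Python
(`necrotext.generate_corpus`, `necrotext.search_records`,
`necrotext.performance_metrics`).

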