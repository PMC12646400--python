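"""TF-IDF candidate-term generation and partial-word lookup.

The selectable search-term list is built by scoring every distinct word of
every record with tf·idf — how characteristic the word is of that record
relative to the whole corpus — and collating the top-N words of each record
(N = 40 by default; 20/10/5 in the sensitivity sweep).

Two scoring variants are shipped:

``tfidf`` (default)
    score = tf(term, record) · ln(N / df(term)), no smoothing, no stop list.
``freq_ratio``
    score = tf(term, record) / total corpus occurrences of term — a raw
    within-record vs corpus-wide frequency ratio.

The per-record ranking tie-break is (score desc, tf desc, term asc), which
makes top-N lists nested in N and runs reproducible regardless of record
order.  For a single-record corpus every idf is ln(1) = 0, so the tie-break
degrades gracefully to plain term-frequency ranking.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import DEFAULT_SCHEMA, CorpusSchema, NecropsyRecord
from .errors import UsageError
from .text_engine import tokenize

__all__ = [
    "TermScore",
    "CandidateList",
    "record_term_counts",
    "tfidf_scores",
    "candidate_terms",
    "match_terms",
]

_VARIANTS = ("tfidf", "freq_ratio")


@dataclass(frozen=True)
class TermScore:
    term: str
    accession_id: str
    tf: int
    df: int
    score: float


@dataclass(frozen=True)
class CandidateList:
    """Union of each record's top-N terms, with provenance."""

    top_n: int
    terms: tuple[str, ...]  # sorted
    provenance: dict[str, frozenset[str]]  # term -> contributing accessions


def record_term_counts(record: NecropsyRecord, schema: CorpusSchema = DEFAULT_SCHEMA) -> Counter:
    """Normalized word-token counts over the record's searchable fields.

    Uses the search engine's tokenizer so every candidate term is guaranteed
    to be searchable; punctuation is dropped, numbers are kept.
    """
    counts: Counter = Counter()
    for col in schema.searchable_columns:
        for tok in tokenize(record.narrative_fields.get(col, "")):
            if not tok.is_punctuation:
                counts[tok.normalized] += 1
    return counts


def _corpus_counts(
    corpus: Sequence[NecropsyRecord], schema: CorpusSchema
) -> tuple[list[Counter], Counter, Counter]:
    per_record = [record_term_counts(rec, schema) for rec in corpus]
    df: Counter = Counter()
    totals: Counter = Counter()
    for counts in per_record:
        df.update(counts.keys())
        totals.update(counts)
    return per_record, df, totals


def tfidf_scores(
    corpus: Sequence[NecropsyRecord],
    schema: CorpusSchema = DEFAULT_SCHEMA,
    variant: str = "tfidf",
) -> list[TermScore]:
    """One score per (record, distinct word in its searchable fields)."""
    if len(corpus) == 0:
        raise UsageError("cannot score an empty corpus")
    if variant not in _VARIANTS:
        raise UsageError(f"unknown scoring variant {variant!r}; choose from {_VARIANTS}")
    per_record, df, totals = _corpus_counts(corpus, schema)
    n = len(corpus)
    scores: list[TermScore] = []
    for rec, counts in zip(corpus, per_record):
        for term in sorted(counts):
            tf = counts[term]
            if variant == "tfidf":
                score = tf * math.log(n / df[term])
            else:
                score = tf / totals[term]
            scores.append(
                TermScore(term=term, accession_id=rec.accession_id, tf=tf, df=df[term], score=score)
            )
    return scores


def candidate_terms(
    corpus: Sequence[NecropsyRecord],
    schema: CorpusSchema = DEFAULT_SCHEMA,
    top_n: int = 40,
    variant: str = "tfidf",
) -> CandidateList:
    """Collate each record's ``top_n`` highest-scoring words into one list."""
    if top_n < 1:
        raise UsageError("top_n must be >= 1")
    if variant not in _VARIANTS:
        raise UsageError(f"unknown scoring variant {variant!r}; choose from {_VARIANTS}")
    if len(corpus) == 0:
        raise UsageError("cannot derive candidates from an empty corpus")
    per_record, df, totals = _corpus_counts(corpus, schema)
    n = len(corpus)
    provenance: dict[str, set[str]] = {}
    for rec, counts in zip(corpus, per_record):
        if variant == "tfidf":
            key = lambda t: (-counts[t] * math.log(n / df[t]), -counts[t], t)
        else:
            key = lambda t: (-counts[t] / totals[t], -counts[t], t)
        for term in sorted(counts, key=key)[:top_n]:
            provenance.setdefault(term, set()).add(rec.accession_id)
    return CandidateList(
        top_n=top_n,
        terms=tuple(sorted(provenance)),
        provenance={t: frozenset(a) for t, a in provenance.items()},
    )


def match_terms(candidates: CandidateList, pattern: str) -> list[str]:
    """Case-insensitive partial-word lookup within the candidate list.

    An empty pattern returns the whole (sorted) list.
    """
    p = pattern.lower()
    return [t for t in candidates.terms if p in t]
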