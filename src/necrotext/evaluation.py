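"""Retrieval evaluation against a manually curated reference set.

Covers: confusion counts (TP/FP/FN — TN is never used), recall / precision /
F1, three-letter word-stem counting of a search-term vocabulary,
misclassification-code propagation and summaries, per-tester metric
aggregation, and the top-N TF-IDF sensitivity sweep.

Misclassification codes
-----------------------
Each erroneously retrieved (FP) or missed (FN) accession carries exactly one
letter code naming the cause of the error:

====  =====================================================================
R     Record structure (e.g. a history-section mention with no pathology)
S     Search term use (term not selected, or a non-specific term selected)
I     Interpretation during manual review (finding included/excluded by
      reviewer judgment rather than explicit wording)
G     Grammatical error (punctuation misplaces the negation window)
T     Typography (misspellings / variants escaping the term list or the
      negation rule)
U     Unknown
====  =====================================================================

Codes are assigned by human judgment; what is automated here is the
*propagation* of codes from an already-annotated dataset to further testers'
FP/FN sets by accession match, returning the unmatched residual for manual
coding.  Percentages are reported rounded half-up to one decimal place.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, Set

from .corpus_io import DEFAULT_SCHEMA, CorpusSchema, NecropsyRecord
from .errors import DataError, UsageError
from .term_candidates import candidate_terms
from .text_engine import SearchQuery, search_records

__all__ = [
    "CODES",
    "DIRECTIONS",
    "ReferenceSet",
    "ConfusionCounts",
    "PerformanceMetrics",
    "MisclassificationAnnotation",
    "CodeSummary",
    "MetricAggregate",
    "SweepCondition",
    "confusion_counts",
    "performance_metrics",
    "stem_count",
    "propagate_annotations",
    "summarize_codes",
    "code_percentage",
    "aggregate_metrics",
    "tfidf_sweep",
]

CODES = ("R", "S", "I", "G", "T", "U")
DIRECTIONS = ("FP", "FN")


@dataclass(frozen=True)
class ReferenceSet:
    """Gold-standard positive accessions for one clinicopathologic finding."""

    finding_name: str
    positive_accessions: frozenset[str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Recall, precision and their harmonic mean (F1).

    ``recall`` is None when the reference set is empty, ``precision`` is None
    when nothing was retrieved; ``f1`` is 0 whenever tp = 0.  Degenerate
    cases are therefore flagged rather than silently reported as 0.
    """

    recall: float | None
    precision: float | None
    f1: float


@dataclass(frozen=True)
class MisclassificationAnnotation:
    accession_id: str
    direction: str  # "FP" or "FN"
    code: str  # one of CODES

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.code not in CODES:
            raise ValueError(f"code must be one of {CODES}")


@dataclass(frozen=True)
class CodeSummary:
    """Per-code counts and percentages for one error direction."""

    direction: str
    n: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float | None]  # None when n == 0


@dataclass(frozen=True)
class MetricAggregate:
    metric: str
    mean: float
    sd: float | None  # sample sd; None for a single tester
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class SweepCondition:
    """One top-N condition of the TF-IDF sweep."""

    top_n: int
    effective_terms: frozenset[str]
    counts: ConfusionCounts
    metrics: PerformanceMetrics
    empty_query: bool


def confusion_counts(retrieved: Set[str], reference: ReferenceSet) -> ConfusionCounts:
    """TP/FP/FN of a retrieved accession set against the reference positives."""
    retrieved = set(retrieved)
    positives = reference.positive_accessions
    return ConfusionCounts(
        tp=len(retrieved & positives),
        fp=len(retrieved - positives),
        fn=len(positives - retrieved),
    )


def performance_metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """recall = tp/(tp+fn); precision = tp/(tp+fp); f1 = 2PR/(P+R)."""
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    if c.tp == 0:
        f1 = 0.0
    else:
        assert recall is not None and precision is not None
        f1 = 2 * precision * recall / (precision + recall)
    return PerformanceMetrics(recall=recall, precision=precision, f1=f1)


def stem_count(terms: Iterable[str]) -> int:
    """Number of distinct three-letter stems (leading trigrams) of the terms.

    Terms shorter than three characters contribute their whole form.  Used to
    quantify how broad the vocabulary describing a finding is.
    """
    return len({t.lower()[:3] for t in terms})


def propagate_annotations(
    targets: Set[tuple[str, str]],
    annotated: Sequence[MisclassificationAnnotation],
) -> tuple[list[MisclassificationAnnotation], set[tuple[str, str]]]:
    """Copy codes from an annotated dataset onto matching (accession,
    direction) targets; return what remains for manual coding.

    Raises :class:`DataError` on conflicting duplicate codes in ``annotated``.
    """
    codebook: dict[tuple[str, str], str] = {}
    for ann in annotated:
        key = (ann.accession_id, ann.direction)
        if key in codebook and codebook[key] != ann.code:
            raise DataError(
                f"conflicting codes for accession {ann.accession_id!r} "
                f"direction {ann.direction}: {codebook[key]} vs {ann.code}"
            )
        codebook[key] = ann.code
    propagated: list[MisclassificationAnnotation] = []
    residual: set[tuple[str, str]] = set()
    for key in sorted(targets):
        if key in codebook:
            propagated.append(
                MisclassificationAnnotation(key[0], key[1], codebook[key])
            )
        else:
            residual.add(key)
    return propagated, residual


def code_percentage(x: int, n: int) -> float:
    """100·x/n rounded half-up to one decimal place (exact rational arithmetic)."""
    if n == 0:
        raise UsageError("percentage undefined for n = 0")
    return float(
        (Decimal(100 * x) / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def summarize_codes(
    annotations: Sequence[MisclassificationAnnotation], direction: str
) -> CodeSummary:
    """Per-code count and percentage-of-direction-total summary."""
    if direction not in DIRECTIONS:
        raise UsageError(f"direction must be one of {DIRECTIONS}")
    if any(a.direction != direction for a in annotations):
        raise UsageError("all annotations must share the summarised direction")
    counts = {code: 0 for code in CODES}
    for ann in annotations:
        counts[ann.code] += 1
    n = len(annotations)
    percentages: dict[str, float | None] = {
        code: (code_percentage(x, n) if n > 0 else None) for code, x in counts.items()
    }
    return CodeSummary(direction=direction, n=n, counts=counts, percentages=percentages)


def aggregate_metrics(
    per_tester: Sequence[PerformanceMetrics],
) -> dict[str, MetricAggregate]:
    """Mean, sample (n-1) standard deviation, and range of each metric across
    testers.  Undefined (None) recalls/precisions are excluded from their
    metric's aggregate."""
    if not per_tester:
        raise UsageError("need at least one tester")
    out: dict[str, MetricAggregate] = {}
    for metric in ("recall", "precision", "f1"):
        values = [
            v for v in (getattr(m, metric) for m in per_tester) if v is not None
        ]
        if not values:
            continue
        out[metric] = MetricAggregate(
            metric=metric,
            mean=statistics.fmean(values),
            sd=statistics.stdev(values) if len(values) > 1 else None,
            minimum=min(values),
            maximum=max(values),
            n=len(values),
        )
    return out


def tfidf_sweep(
    corpus: Sequence[NecropsyRecord],
    schema: CorpusSchema,
    recorded_terms: Set[str],
    reference: ReferenceSet,
    top_ns: Sequence[int] = (40, 20, 10, 5),
    *,
    variant: str = "tfidf",
    negator_lexicon: frozenset[str] | None = None,
    window_size: int = 10,
) -> list[SweepCondition]:
    """Re-run a tester's recorded query under shrinking candidate lists.

    For each top-N condition the effective query is the intersection of the
    recorded terms with the top-N candidate list; conditions whose effective
    query is empty yield tp = 0 and are flagged.
    """
    if not top_ns:
        raise UsageError("top_ns must be non-empty")
    recorded = {t.lower() for t in recorded_terms}
    conditions: list[SweepCondition] = []
    for top_n in top_ns:
        available = set(candidate_terms(corpus, schema, top_n, variant).terms)
        effective = frozenset(recorded & available)
        if not effective:
            counts = ConfusionCounts(tp=0, fp=0, fn=len(reference.positive_accessions))
            conditions.append(
                SweepCondition(
                    top_n=top_n,
                    effective_terms=effective,
                    counts=counts,
                    metrics=performance_metrics(counts),
                    empty_query=True,
                )
            )
            continue
        kwargs = {} if negator_lexicon is None else {"negator_lexicon": negator_lexicon}
        query = SearchQuery(terms=frozenset(effective), window_size=window_size, **kwargs)
        result = search_records(corpus, query, schema)
        counts = confusion_counts(set(result.accession_ids), reference)
        conditions.append(
            SweepCondition(
                top_n=top_n,
                effective_terms=effective,
                counts=counts,
                metrics=performance_metrics(counts),
                empty_query=False,
            )
        )
    return conditions
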