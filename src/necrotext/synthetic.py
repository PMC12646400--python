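"""Seeded synthetic necropsy corpora with exact ground truth.

The generator emulates the statistical structure of a wildlife pathology
register export: multi-field records (history, gross findings,
histopathology, diagnosis, comments) whose narrative prose is built from a
fixed template bank with slot filling, so the position, surface form and
negation status of every planted finding mention is known exactly.  Each run
emits the corpus, one gold-standard reference set per finding, and a
:class:`PlantedLog` from which a test oracle can predict — without running
the search engine — exactly which records any term query must retrieve.

Findings differ in vocabulary breadth: a *narrow* finding (external oiling)
is described by a handful of words sharing one stem, a *broad* one
(starvation) by many synonyms with distinct stems.  On top of the clean
mentions, "traps" are planted at configurable rates, mirroring the error
mechanisms a rule-based negation searcher is known to exhibit:

``negation``       a negated mention in a negative record ("No evidence of
                   oiling is seen.") — correctly suppressed by the engine.
``missing_comma``  a positive record whose only mention sits in the scope of
                   an earlier negator because a comma is missing
                   ("Abnormalities not found but lacerations present on the
                   body.") — an engine false negative.
``slash_join``     "No signs of X/ Y identified." in a negative record: the
                   slash ends the phrase, so Y escapes the negator — an
                   engine false positive.
``history_only``   the finding named in the history field only, with no
                   pathology ("recovered during the regional oil event") —
                   a false positive when history is searchable.
``typo``           a positive record expressed only through a misspelled
                   variant — a false negative unless the variant is among
                   the query terms.

Template filler prose contains no finding-vocabulary words and no negators,
so the planted log accounts for every mention the engine can find.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import DEFAULT_SCHEMA, CorpusSchema, NecropsyRecord
from .errors import UsageError
from .evaluation import ConfusionCounts, ReferenceSet, confusion_counts
from .text_engine import DEFAULT_NEGATORS, SearchQuery

__all__ = [
    "FindingProfile",
    "TrapRates",
    "PlantedMention",
    "PlantedLog",
    "default_profiles",
    "generate_corpus",
    "predicted_retrieved",
    "expected_outcomes",
]

_PATHOLOGY_FIELDS = ("gross_findings", "histopathology", "diagnosis")


@dataclass(frozen=True)
class FindingProfile:
    """Vocabulary and prevalence of one clinicopathologic finding.

    ``vocabulary`` lists the single-word searchable forms; ``weights`` give
    their relative use when planting clean mentions (uniform if omitted);
    ``typo_variants`` flags which vocabulary entries are misspellings used
    only by the typo trap.
    """

    name: str
    vocabulary: tuple[str, ...]
    prevalence: float
    breadth: str = "broad"  # "narrow" | "broad"
    weights: tuple[float, ...] | None = None
    typo_variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.vocabulary:
            raise UsageError(f"profile {self.name!r}: vocabulary must be non-empty")
        if not 0.0 <= self.prevalence <= 1.0:
            raise UsageError(f"profile {self.name!r}: prevalence must be in [0, 1]")
        if self.breadth not in ("narrow", "broad"):
            raise UsageError(f"profile {self.name!r}: breadth must be narrow|broad")
        if self.weights is not None and len(self.weights) != len(self.vocabulary):
            raise UsageError(f"profile {self.name!r}: weights must match vocabulary")
        if not self.typo_variants <= set(self.vocabulary):
            raise UsageError(f"profile {self.name!r}: typo variants must be vocabulary words")
        clean = tuple(w for w in self.vocabulary if w not in self.typo_variants)
        if not clean:
            raise UsageError(f"profile {self.name!r}: needs at least one non-typo word")

    @property
    def clean_vocabulary(self) -> tuple[str, ...]:
        return tuple(w for w in self.vocabulary if w not in self.typo_variants)


@dataclass(frozen=True)
class TrapRates:
    """Per-record planting probabilities of each trap mechanism."""

    negation: float = 0.10
    missing_comma: float = 0.02
    slash_join: float = 0.02
    history_only: float = 0.03
    typo: float = 0.05

    def __post_init__(self) -> None:
        for name in ("negation", "missing_comma", "slash_join", "history_only", "typo"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise UsageError(f"trap rate {name} must be in [0, 1], got {rate}")
        if self.missing_comma + self.typo > 1.0:
            raise UsageError("missing_comma + typo rates must not exceed 1")

    @classmethod
    def none(cls) -> "TrapRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PlantedMention:
    """One planted occurrence of a finding word, with the negation status the
    search engine will effectively see."""

    accession_id: str
    finding: str
    field: str
    term: str
    effective_negated: bool
    trap: str | None  # negation|missing_comma|slash_join|history_only|typo|None


@dataclass(frozen=True)
class PlantedLog:
    """Full ground truth of a generated corpus."""

    seed: int
    status: Mapping[str, Mapping[str, bool]]  # finding -> accession -> positive?
    mentions: tuple[PlantedMention, ...]

    def reference_set(self, finding: str) -> ReferenceSet:
        return ReferenceSet(
            finding_name=finding,
            positive_accessions=frozenset(
                acc for acc, pos in self.status[finding].items() if pos
            ),
        )


def default_profiles() -> list[FindingProfile]:
    """Four findings mirroring the narrow-to-broad vocabulary spectrum of a
    penguin necropsy register: external oiling (narrow, one stem), traumatic
    injury (broad), diphtheritic stomatitis (narrow but typo-prone) and
    starvation (broad, many distinct stems)."""
    return [
        FindingProfile(
            name="Oil",
            vocabulary=("oil", "oiled", "oiling"),
            weights=(0.6, 0.25, 0.15),
            prevalence=0.15,
            breadth="narrow",
        ),
        FindingProfile(
            name="Trauma",
            vocabulary=(
                "trauma",
                "traumatic",
                "lacerations",
                "fracture",
                "predation",
                "bruising",
            ),
            prevalence=0.30,
            breadth="broad",
        ),
        FindingProfile(
            name="DipStom",
            vocabulary=("stomatitis", "diphtheritic", "diptheritic", "diptheric"),
            weights=(0.5, 0.3, 0.1, 0.1),
            prevalence=0.25,
            breadth="narrow",
            typo_variants=frozenset({"diptheritic", "diptheric"}),
        ),
        FindingProfile(
            name="Starve",
            vocabulary=(
                "starvation",
                "starved",
                "emaciated",
                "emaciation",
                "skinny",
                "thin",
                "cachexia",
            ),
            prevalence=0.30,
            breadth="broad",
        ),
    ]


# Filler prose: vetted to contain neither finding-vocabulary words nor
# negators, so every engine-findable mention is in the planted log.
_HISTORY_FILLER = (
    "Found dead on the beach by a member of the public.",
    "Carcass submitted frozen after collection from the colony.",
    "Bird located deceased at the nest site during routine monitoring.",
)
_GROSS_FILLER = (
    "The carcass is in a fair state of preservation.",
    "Plumage is intact and waterproofing appears adequate.",
    "Internal organs appear grossly unremarkable.",
)
_HISTO_FILLER = (
    "Sections of liver and kidney show autolytic change only.",
    "Examined tissues are within normal limits.",
)
_DIAG_FILLER = (
    "Cause of death undetermined pending further testing.",
    "Open diagnosis.",
)
_COMMENT_FILLER = (
    "Further toxicology declined by the submitter.",
    "Case discussed with the submitting ranger.",
)
_ORGANS = ("liver", "ventriculus", "pectoral muscle", "skin", "oral cavity", "air sacs")

_POSITIVE_TEMPLATES = (
    "Gross examination reveals {term} affecting the {organ}.",
    "There is marked {term} involving the {organ}.",
    "Severe {term} noted over the {organ}.",
)
_DIAGNOSIS_TEMPLATE = "Morphologic diagnosis: {term}."
_NEGATION_TEMPLATES = (
    "No evidence of {term} is seen.",
    "There is no {term} identified.",
)
_MISSING_COMMA_TEMPLATE = "Abnormalities not found but {term} present on the body."
_SLASH_TEMPLATE = "No signs of {a}/ {b} identified."
_HISTORY_ONLY_TEMPLATE = "History notes the bird was recovered during the regional {term} event."


def _pick(rng: random.Random, profile: FindingProfile) -> str:
    words = profile.clean_vocabulary
    if profile.weights is None:
        return rng.choice(words)
    weights = [w for word, w in zip(profile.vocabulary, profile.weights) if word in words]
    return rng.choices(words, weights=weights, k=1)[0]


def generate_corpus(
    profiles: Sequence[FindingProfile] | None = None,
    traps: TrapRates | None = None,
    n_records: int = 200,
    seed: int = 0,
) -> tuple[list[NecropsyRecord], dict[str, ReferenceSet], PlantedLog]:
    """Generate a corpus, its per-finding reference sets, and the planted log.

    Deterministic under ``seed``: the same arguments always produce
    byte-identical records and logs.
    """
    if n_records < 1:
        raise UsageError("n_records must be >= 1")
    profiles = list(default_profiles()) if profiles is None else list(profiles)
    if not profiles:
        raise UsageError("profiles must be non-empty")
    traps = TrapRates() if traps is None else traps

    seen: dict[str, str] = {}
    for p in profiles:
        for w in p.vocabulary:
            if w in seen and seen[w] != p.name:
                raise UsageError(
                    f"vocabularies must be disjoint: {w!r} in both {seen[w]!r} and {p.name!r}"
                )
            seen[w] = p.name

    rng = random.Random(seed)
    records: list[NecropsyRecord] = []
    mentions: list[PlantedMention] = []
    status: dict[str, dict[str, bool]] = {p.name: {} for p in profiles}

    for i in range(1, n_records + 1):
        acc = f"SYN-{i:04d}"
        species = rng.choice(("korora", "hoiho"))
        date = f"{rng.randint(2015, 2024)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        fields: dict[str, list[str]] = {
            "history": [rng.choice(_HISTORY_FILLER)],
            "gross_findings": [rng.choice(_GROSS_FILLER)],
            "histopathology": [rng.choice(_HISTO_FILLER)],
            "diagnosis": [rng.choice(_DIAG_FILLER)],
            "comments": [rng.choice(_COMMENT_FILLER)],
        }

        def plant(finding: str, fld: str, term: str, negated: bool, trap: str | None) -> None:
            mentions.append(
                PlantedMention(
                    accession_id=acc,
                    finding=finding,
                    field=fld,
                    term=term,
                    effective_negated=negated,
                    trap=trap,
                )
            )

        for profile in profiles:
            positive = rng.random() < profile.prevalence
            status[profile.name][acc] = positive
            if positive:
                roll = rng.random()
                if roll < traps.missing_comma:
                    # Only mention sits after "not found but": engine-negated.
                    term = _pick(rng, profile)
                    fields["gross_findings"].append(
                        _MISSING_COMMA_TEMPLATE.format(term=term)
                    )
                    plant(profile.name, "gross_findings", term, True, "missing_comma")
                elif roll < traps.missing_comma + traps.typo and profile.typo_variants:
                    term = rng.choice(sorted(profile.typo_variants))
                    fld = rng.choice(("gross_findings", "histopathology"))
                    fields[fld].append(
                        rng.choice(_POSITIVE_TEMPLATES).format(
                            term=term, organ=rng.choice(_ORGANS)
                        )
                    )
                    plant(profile.name, fld, term, False, "typo")
                else:
                    for term in {_pick(rng, profile) for _ in range(rng.choice((1, 1, 2)))}:
                        fld = rng.choice(_PATHOLOGY_FIELDS)
                        if fld == "diagnosis":
                            fields[fld].append(_DIAGNOSIS_TEMPLATE.format(term=term))
                        else:
                            fields[fld].append(
                                rng.choice(_POSITIVE_TEMPLATES).format(
                                    term=term, organ=rng.choice(_ORGANS)
                                )
                            )
                        plant(profile.name, fld, term, False, None)
            else:
                if rng.random() < traps.negation:
                    term = _pick(rng, profile)
                    fields["gross_findings"].append(
                        rng.choice(_NEGATION_TEMPLATES).format(term=term)
                    )
                    plant(profile.name, "gross_findings", term, True, "negation")
                if rng.random() < traps.slash_join and len(profile.clean_vocabulary) >= 2:
                    a, b = rng.sample(profile.clean_vocabulary, 2)
                    fields["gross_findings"].append(_SLASH_TEMPLATE.format(a=a, b=b))
                    plant(profile.name, "gross_findings", a, True, "slash_join")
                    plant(profile.name, "gross_findings", b, False, "slash_join")
                if rng.random() < traps.history_only:
                    term = _pick(rng, profile)
                    fields["history"].append(_HISTORY_ONLY_TEMPLATE.format(term=term))
                    plant(profile.name, "history", term, False, "history_only")

        records.append(
            NecropsyRecord(
                accession_id=acc,
                structured_fields={"species": species, "date": date},
                narrative_fields={k: " ".join(v) for k, v in fields.items()},
            )
        )

    log = PlantedLog(
        seed=seed,
        status={k: dict(v) for k, v in status.items()},
        mentions=tuple(mentions),
    )
    references = {p.name: log.reference_set(p.name) for p in profiles}
    return records, references, log


def predicted_retrieved(
    log: PlantedLog,
    query: SearchQuery,
    searchable_columns: Iterable[str] | None = None,
) -> frozenset[str]:
    """Accessions the engine must retrieve, predicted from planted events
    alone: any record with a planted, effectively non-negated mention of a
    query term in a searchable field."""
    searchable = (
        frozenset(DEFAULT_SCHEMA.searchable_columns)
        if searchable_columns is None
        else frozenset(searchable_columns)
    )
    return frozenset(
        m.accession_id
        for m in log.mentions
        if m.term.lower() in query.terms
        and m.field in searchable
        and not m.effective_negated
    )


def expected_outcomes(
    log: PlantedLog,
    query: SearchQuery,
    reference: ReferenceSet,
    searchable_columns: Iterable[str] | None = None,
) -> ConfusionCounts:
    """Predicted confusion counts for ``query`` against ``reference``."""
    return confusion_counts(predicted_retrieved(log, query, searchable_columns), reference)
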