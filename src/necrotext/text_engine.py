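"""Tokenization, phrase windows, rule-based negation detection, retrieval.

The retrieval rule: a record is returned for a query iff some searchable
field contains at least one occurrence of a query term *without* a negator
word ("no", "not", "never", ...) in the same phrase.  A phrase is the span
around the matched term bounded by the first punctuation mark on each side,
capped at ``window_size`` word tokens per side (ten by default).

Punctuation is load-bearing: a comma between a negator and the term breaks
the negation ("No, signs of oiling" is a *positive* mention of "oiling"),
and a slash is a phrase boundary ("no signs of trauma/ predation" leaves
"predation" un-negated).  Conversely a missing comma lets a negator leak
into a genuinely positive clause ("Stomatitis not found but multiple
lacerations present on the body" negates "lacerations").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import DEFAULT_SCHEMA, CorpusSchema, NecropsyRecord
from .errors import UsageError

__all__ = [
    "DEFAULT_NEGATORS",
    "DEFAULT_PHRASE_BOUNDARIES",
    "Token",
    "PhraseWindow",
    "Mention",
    "SearchQuery",
    "RetrievalResult",
    "tokenize",
    "phrase_window",
    "detect_negation",
    "find_mentions",
    "search_records",
    "count_unique",
]

#: Default negator lexicon; user-extensible via SearchQuery/config.
DEFAULT_NEGATORS = frozenset(
    {"no", "not", "never", "neither", "nor", "without", "absent"}
)

#: Punctuation marks that end a phrase.  The hyphen is deliberately absent:
#: hyphenated compounds split into word tokens but do not break phrases.
DEFAULT_PHRASE_BOUNDARIES = frozenset(
    {".", ",", ";", ":", "!", "?", "/", "(", ")", "\n"}
)

# Words are runs of letters/digits; every other non-space character is its
# own punctuation token.  The newline is matched explicitly so it can act as
# a phrase boundary.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|\n|[^\w\s]")


@dataclass(frozen=True)
class Token:
    surface: str
    normalized: str
    start: int
    end: int
    is_punctuation: bool
    is_phrase_boundary: bool


@dataclass(frozen=True)
class PhraseWindow:
    """Inclusive token-index bounds of the phrase around an anchor token."""

    left: int
    right: int


@dataclass(frozen=True)
class Mention:
    """One occurrence of a query term, with its negation verdict."""

    accession_id: str
    term: str
    field_name: str
    anchor_index: int
    window: PhraseWindow
    negated: bool
    negator: str | None = None

    def __post_init__(self) -> None:
        if self.negated != (self.negator is not None):
            raise ValueError("negated must hold exactly when a negator is recorded")


@dataclass(frozen=True)
class SearchQuery:
    """A term query plus the negation-detection settings it runs under."""

    terms: frozenset[str]
    negator_lexicon: frozenset[str] = DEFAULT_NEGATORS
    window_size: int = 10
    phrase_boundaries: frozenset[str] = DEFAULT_PHRASE_BOUNDARIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(t.lower() for t in self.terms))
        object.__setattr__(
            self, "negator_lexicon", frozenset(w.lower() for w in self.negator_lexicon)
        )
        if self.window_size < 1:
            raise UsageError("window_size must be >= 1")


@dataclass(frozen=True)
class RetrievalResult:
    query: SearchQuery
    accession_ids: frozenset[str]
    mentions: tuple[Mention, ...]  # the non-negated mentions that triggered retrieval


def tokenize(text: str, boundary_set: Iterable[str] | None = None) -> list[Token]:
    """Split text into word and punctuation tokens with character offsets.

    Concatenating token surfaces with the skipped inter-token characters
    reconstructs the input exactly.  Each punctuation mark in the boundary
    set is flagged as a phrase boundary.
    """
    bset = DEFAULT_PHRASE_BOUNDARIES if boundary_set is None else frozenset(boundary_set)
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        s = m.group()
        is_word = s[0].isalnum()
        tokens.append(
            Token(
                surface=s,
                normalized=s.lower(),
                start=m.start(),
                end=m.end(),
                is_punctuation=not is_word,
                is_phrase_boundary=(not is_word) and s in bset,
            )
        )
    return tokens


def phrase_window(
    tokens: Sequence[Token],
    anchor: int,
    window_size: int = 10,
    boundary_set: Iterable[str] | None = None,
) -> PhraseWindow:
    """Phrase bounds around ``anchor``: stop at the first phrase-boundary
    punctuation or after ``window_size`` word tokens per side, whichever
    comes first.  Boundary tokens are excluded from the window; non-boundary
    punctuation passes through without counting as a word.
    """
    if not 0 <= anchor < len(tokens):
        raise UsageError(f"anchor index {anchor} out of range")
    if tokens[anchor].is_punctuation:
        raise UsageError("anchor must be a word token")
    bset = None if boundary_set is None else frozenset(boundary_set)

    def is_boundary(tok: Token) -> bool:
        if not tok.is_punctuation:
            return False
        return tok.surface in bset if bset is not None else tok.is_phrase_boundary

    left = anchor
    words = 0
    i = anchor - 1
    while i >= 0 and words < window_size:
        tok = tokens[i]
        if is_boundary(tok):
            break
        left = i
        if not tok.is_punctuation:
            words += 1
        i -= 1

    right = anchor
    words = 0
    i = anchor + 1
    while i < len(tokens) and words < window_size:
        tok = tokens[i]
        if is_boundary(tok):
            break
        right = i
        if not tok.is_punctuation:
            words += 1
        i += 1

    return PhraseWindow(left=left, right=right)


def detect_negation(
    tokens: Sequence[Token],
    anchor: int,
    query: SearchQuery,
    accession_id: str = "",
    field_name: str = "",
) -> Mention:
    """Negation verdict for the term occurrence at ``anchor``.

    The mention is negated iff some word token inside its phrase window,
    other than the anchor itself, belongs to the negator lexicon; the first
    such token left-to-right is recorded.  A token that is simultaneously a
    query term and a negator counts as a match, never as its own negator.
    """
    term = tokens[anchor].normalized
    if term not in query.terms:
        raise UsageError(f"anchor token {term!r} is not a query term")
    window = phrase_window(tokens, anchor, query.window_size, query.phrase_boundaries)
    negator: str | None = None
    for i in range(window.left, window.right + 1):
        if i == anchor:
            continue
        tok = tokens[i]
        if not tok.is_punctuation and tok.normalized in query.negator_lexicon:
            negator = tok.normalized
            break
    return Mention(
        accession_id=accession_id,
        term=term,
        field_name=field_name,
        anchor_index=anchor,
        window=window,
        negated=negator is not None,
        negator=negator,
    )


def find_mentions(
    record: NecropsyRecord,
    query: SearchQuery,
    schema: CorpusSchema = DEFAULT_SCHEMA,
) -> list[Mention]:
    """All mentions (negated and not) of the query terms in the record's
    searchable fields, in field order then text order."""
    mentions: list[Mention] = []
    for field_name in schema.searchable_columns:
        text = record.narrative_fields.get(field_name, "")
        tokens = tokenize(text, query.phrase_boundaries)
        for i, tok in enumerate(tokens):
            if not tok.is_punctuation and tok.normalized in query.terms:
                mentions.append(
                    detect_negation(tokens, i, query, record.accession_id, field_name)
                )
    return mentions


def search_records(
    corpus: Sequence[NecropsyRecord],
    query: SearchQuery,
    schema: CorpusSchema = DEFAULT_SCHEMA,
) -> RetrievalResult:
    """Retrieve the unique records with >= 1 non-negated mention of any
    query term in any searchable field."""
    if not query.terms:
        raise UsageError(
            "query has no terms; use term_candidates.match_terms to select some"
        )
    hits: set[str] = set()
    positive: list[Mention] = []
    for record in corpus:
        for mention in find_mentions(record, query, schema):
            if not mention.negated:
                hits.add(record.accession_id)
                positive.append(mention)
    return RetrievalResult(
        query=query, accession_ids=frozenset(hits), mentions=tuple(positive)
    )


def count_unique(result: RetrievalResult) -> int:
    """Number of unique records retrieved across all query terms."""
    return len(result.accession_ids)
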