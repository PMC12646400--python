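"""Read and write CSV aggregations of necropsy records.

A corpus is a flat CSV file, one row per accession, whose column layout is
described by a :class:`CorpusSchema`.  Pathology registers differ in their
export layout, so the schema is user-supplied configuration; a shipped
default covers the common shape of a necropsy export (signalment columns
followed by the narrative sections of the report).

Cells are read and written verbatim as text — RFC 4180 quoting, UTF-8,
header row required — so that narrative fields containing commas, quotes or
newlines survive a round trip bit-exactly.  Leading/trailing whitespace is
preserved; normalisation is the tokenizer's job, not the reader's.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, CorpusError, SchemaError

__all__ = [
    "CorpusSchema",
    "NecropsyRecord",
    "DEFAULT_SCHEMA",
    "load_schema",
    "read_records",
    "write_retrieved",
]


@dataclass(frozen=True)
class CorpusSchema:
    """Column layout of a corpus CSV.

    Parameters
    ----------
    accession_column
        Column holding the unique accession identifier.
    structured_columns
        Ordered signalment/submission metadata columns (species, date, ...).
    narrative_columns
        Ordered free-text report sections (history, gross findings, ...).
    searchable_columns
        Subset of ``narrative_columns`` the search engine scans.  Defaults to
        all narrative columns; excluding the history field is a supported
        configuration for registers where history text does not reflect
        pathology.
    species_column
        Which structured column, if any, holds the species name.
    """

    accession_column: str = "accession"
    structured_columns: tuple[str, ...] = ("species", "date")
    narrative_columns: tuple[str, ...] = (
        "history",
        "gross_findings",
        "histopathology",
        "diagnosis",
        "comments",
    )
    searchable_columns: tuple[str, ...] = field(default=())
    species_column: str | None = "species"

    def __post_init__(self) -> None:
        if not self.narrative_columns:
            raise ConfigError("schema must declare at least one narrative column")
        if self.accession_column in self.narrative_columns:
            raise ConfigError(
                f"accession column {self.accession_column!r} cannot also be narrative"
            )
        if not self.searchable_columns:
            object.__setattr__(self, "searchable_columns", tuple(self.narrative_columns))
        unknown = set(self.searchable_columns) - set(self.narrative_columns)
        if unknown:
            raise ConfigError(
                f"searchable columns not in narrative columns: {sorted(unknown)}"
            )

    @property
    def columns(self) -> tuple[str, ...]:
        """All columns in file order."""
        return (self.accession_column, *self.structured_columns, *self.narrative_columns)


DEFAULT_SCHEMA = CorpusSchema()


@dataclass(frozen=True)
class NecropsyRecord:
    """One accession: structured metadata plus the free-text report sections."""

    accession_id: str
    structured_fields: Mapping[str, str]
    narrative_fields: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise CorpusError("accession_id must be non-empty")
        if not self.narrative_fields:
            raise CorpusError("narrative_fields must be a non-empty mapping")

    @property
    def species(self) -> str:
        return self.structured_fields.get("species", "")

    def text(self, columns: Iterable[str] | None = None) -> str:
        """Concatenated narrative text of the given (default: all) fields."""
        cols = tuple(columns) if columns is not None else tuple(self.narrative_fields)
        return "\n".join(self.narrative_fields.get(c, "") for c in cols)


def load_schema(path: str | Path) -> CorpusSchema:
    """Load a :class:`CorpusSchema` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"schema file {path} must contain a mapping")
    kwargs = {}
    for key in (
        "accession_column",
        "structured_columns",
        "narrative_columns",
        "searchable_columns",
        "species_column",
    ):
        if key in raw:
            val = raw[key]
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    try:
        return CorpusSchema(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid schema file {path}: {exc}") from exc


def read_records(path: str | Path, schema: CorpusSchema = DEFAULT_SCHEMA) -> list[NecropsyRecord]:
    """Read a corpus CSV into a list of records.

    Row order is preserved and every cell is read as text.  An empty file
    (header only, or zero bytes) yields an empty corpus.

    Raises
    ------
    SchemaError
        If a schema column is missing from the header.
    CorpusError
        If two rows share an accession id.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, restval="")
        header = reader.fieldnames
        if header is None:
            return []
        missing = [c for c in schema.columns if c not in header]
        if missing:
            raise SchemaError(f"corpus file {path} is missing schema column(s): {missing}")
        records: list[NecropsyRecord] = []
        seen: dict[str, int] = {}
        duplicates: list[str] = []
        for row in reader:
            acc = row[schema.accession_column]
            if acc in seen:
                duplicates.append(acc)
            seen[acc] = seen.get(acc, 0) + 1
            records.append(
                NecropsyRecord(
                    accession_id=acc,
                    structured_fields={c: row.get(c, "") for c in schema.structured_columns},
                    narrative_fields={c: row.get(c, "") for c in schema.narrative_columns},
                )
            )
    if duplicates:
        raise CorpusError(f"duplicate accession id(s): {sorted(set(duplicates))}")
    return records


def write_retrieved(
    records: Sequence[NecropsyRecord],
    path: str | Path,
    schema: CorpusSchema = DEFAULT_SCHEMA,
) -> None:
    """Write records to a corpus CSV (header always written).

    Round-trip property: ``read_records(write_retrieved(X))`` reproduces ``X``
    field-for-field.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(schema.columns)
        for rec in records:
            writer.writerow(
                [rec.accession_id]
                + [rec.structured_fields.get(c, "") for c in schema.structured_columns]
                + [rec.narrative_fields.get(c, "") for c in schema.narrative_columns]
            )
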