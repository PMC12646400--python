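import pytest

from necrotext import DEFAULT_SCHEMA, NecropsyRecord


def make_record(accession_id: str, species: str = "korora", **narrative: str) -> NecropsyRecord:
    """Record with the default schema's fields, unspecified ones empty."""
    fields = {col: "" for col in DEFAULT_SCHEMA.narrative_columns}
    unknown = set(narrative) - set(fields)
    if unknown:
        raise ValueError(f"not narrative columns: {unknown}")
    fields.update(narrative)
    return NecropsyRecord(
        accession_id=accession_id,
        structured_fields={"species": species, "date": "2020-01-01"},
        narrative_fields=fields,
    )


@pytest.fixture
def toy_corpus():
    """Five hand-written records exercising matches, negation and traps."""
    return [
        make_record("HW-1", gross_findings="Severe oiling of the plumage observed."),
        make_record("HW-2", gross_findings="No evidence of oiling is seen."),
        make_record("HW-3", gross_findings="No, signs of oiling."),
        make_record("HW-4", gross_findings="no signs of trauma/ predation."),
        make_record(
            "HW-5",
            gross_findings="Stomatitis not found but multiple lacerations present on the body.",
        ),
    ]
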