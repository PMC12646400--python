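"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`UsageError` / :class:`ConfigError`
exit 1, :class:`DataError` (and subclasses) exit 2.
"""


class NecrotextError(Exception):
    """Base class for all package errors."""


class UsageError(NecrotextError):
    """A caller violated an operation's contract (bad arguments, empty query)."""


class ConfigError(NecrotextError):
    """A configuration file or schema definition is invalid."""


class DataError(NecrotextError):
    """Input data violates a corpus invariant."""


class SchemaError(DataError):
    """A required schema column is missing from a corpus file."""


class CorpusError(DataError):
    """Corpus-level invariant violation (e.g. duplicate accession ids)."""
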