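"""Exception hierarchy.

All package-specific failures derive from :class:`StressIdxError` so callers
(and the CLI) can catch one type and report a single human-readable cause.
"""


class StressIdxError(Exception):
    """Base class for all errors raised by stressidx."""


class SchemaError(StressIdxError):
    """Input columns could not be identified (missing or ambiguous)."""


class ParseError(StressIdxError):
    """A cell that must be numeric could not be parsed."""


class ValidationError(StressIdxError):
    """Structurally readable input violates a trial-table invariant."""
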