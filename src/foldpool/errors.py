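"""Exception hierarchy for foldpool.

All package errors derive from :class:`FoldpoolError` so callers can catch
one base class at pipeline boundaries.
"""


class FoldpoolError(Exception):
    """Base class for all foldpool errors."""


class SchemaError(FoldpoolError):
    """An input table is missing a mandatory column."""


class TableValidationError(FoldpoolError):
    """A value in an input table violates its documented bounds."""


class FormatError(FoldpoolError):
    """A ranking-score JSON file is malformed or has an ambiguous dialect."""


class EmptyPoolError(FoldpoolError):
    """An operation that needs at least one prediction received none."""


class MissingScoreError(FoldpoolError):
    """A record lacks the scores needed for the requested operation."""


class MissingBaselineError(FoldpoolError):
    """A gated scenario was applied to an interface without a baseline summary."""


class ConfigError(FoldpoolError):
    """A configuration (plan, weights, generator) is inconsistent."""


class UndefinedAUCError(FoldpoolError):
    """ROC/AUC requested for a truth vector with a single class."""
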