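"""Exception hierarchy for azmap.

Every error raised by the library derives from :class:`AzmapError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class AzmapError(Exception):
    """Base class for all azmap errors."""


class SchemaError(AzmapError):
    """An input table is missing a mandatory column."""


class RowParseError(AzmapError):
    """A row of an input table could not be parsed (reports the row number)."""


class EmptyInputError(AzmapError):
    """An operation received an empty table or collection."""


class OrphanTraceError(AzmapError):
    """A trace refers to an event id absent from the event table."""


class FormatError(AzmapError):
    """A file is structurally malformed (e.g. ragged trace rows)."""


class InvalidOffsetError(AzmapError):
    """An event carries a frame offset < 1."""


class PreconditionError(AzmapError):
    """An operation was called before its prerequisites were computed."""


class InsufficientPointsError(AzmapError):
    """Too few points to build the requested geometry or fit."""


class DegenerateGeometryError(AzmapError):
    """Collinear or otherwise degenerate point set (no 2-D hull exists)."""


class InsufficientDataError(AzmapError):
    """Too few samples for the requested computation."""


class DegenerateNormalizationError(AzmapError):
    """Min-max normalization of a constant trace."""


class UndefinedStatisticError(AzmapError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class GenerationError(AzmapError):
    """The synthetic generator was asked for infeasible geometry."""


class ConfigError(AzmapError):
    """Invalid acquisition or simulation configuration."""
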