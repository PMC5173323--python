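"""Exception hierarchy for ivtrack.

All errors raised deliberately by the library derive from :class:`IvtrackError`
so callers (and the CLI) can catch one base class.
"""


class IvtrackError(Exception):
    """Base class for all ivtrack errors."""


class TrackValidationError(IvtrackError, ValueError):
    """A track or track set violates a structural invariant."""


class FormatError(IvtrackError, ValueError):
    """A delimited track/point table cannot be interpreted."""


class ConfigError(IvtrackError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class PresetNotFoundError(IvtrackError, LookupError):
    """An unknown motility-regime preset was requested."""


class InsufficientDataError(IvtrackError, ValueError):
    """Too few points/timepoints for the requested computation."""


class EmptyCohortError(IvtrackError, ValueError):
    """No tracks remain after exclusions."""


class GeometryError(IvtrackError, ValueError):
    """Spatial geometry is missing, degenerate, or outside the field."""


class UndefinedFractionError(IvtrackError, ZeroDivisionError):
    """A fraction was requested with an empty denominator."""


class DomainError(IvtrackError, ValueError):
    """A scalar input is outside the formula's domain."""


class PipelineError(IvtrackError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
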