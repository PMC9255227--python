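"""Exception hierarchy.

All library errors derive from :class:`OjipError` so callers can catch one
type at pipeline boundaries; subclasses mark which stage rejected the input.
"""


class OjipError(Exception):
    """Base class for all ojipkit errors."""


class InvalidCurveError(OjipError):
    """A transient or MR820 curve violates its structural contract."""


class CoverageError(InvalidCurveError):
    """The time axis does not cover a required cardinal time."""


class NormalizationError(OjipError):
    """Double normalization is undefined (non-inducing curve)."""


class JipUndefinedError(OjipError):
    """A JIP-test ratio hits a zero denominator."""


class UnreachableTargetError(OjipError):
    """No nonnegative Hill-component mix reaches the requested targets."""


class SampleSheetError(OjipError):
    """Sample sheet fails validation."""


class StatisticsError(OjipError):
    """Group comparison cannot be computed."""
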