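"""Exception hierarchy for crustgas.

All package errors derive from :class:`CrustGasError` so callers can catch
pipeline failures with a single except clause while still distinguishing
invalid inputs from genuinely degenerate data.
"""


class CrustGasError(Exception):
    """Base class for all crustgas errors."""


class InvalidInputError(CrustGasError, ValueError):
    """An argument violates a physical or mathematical precondition."""


class InsufficientDataError(CrustGasError):
    """Too few observations to perform the requested estimate."""


class NoNetProductionError(CrustGasError):
    """An isotope interval shows no net gas accumulation (amount2 <= amount1)."""


class DegenerateEndMemberError(CrustGasError):
    """Two-pool mixing requested with identical end members."""


class InvalidCurveError(CrustGasError):
    """A qPCR standard curve is unusable (non-negative slope)."""


class UnsupportedDesignError(CrustGasError):
    """The factorial ANOVA received an unbalanced or incomplete design."""


class UndefinedCorrelationError(CrustGasError):
    """Correlation requested on a zero-variance variable."""


class SchemaError(CrustGasError):
    """A tabular input file failed validation; message names the offending rows."""
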