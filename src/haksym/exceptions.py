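"""Exception hierarchy.

All domain errors derive from :class:`HaksymError` so callers can catch the
package's failures with a single ``except`` clause; numerical failures and
input errors are kept distinct because the command line maps them to
different exit codes.
"""


class HaksymError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(HaksymError, ValueError):
    """A parameter set, condition, or dataset violates its invariants."""


class DegenerateSystemError(HaksymError, ArithmeticError):
    """The kinetic cycle has no unique steady state (zero denominator)."""


class UndefinedReversalError(HaksymError, ValueError):
    """Reversal potential undefined (some concentration is zero)."""


class UndefinedMetricError(HaksymError, ValueError):
    """A derived metric is undefined for the given inputs."""


class InsufficientDataError(HaksymError, ValueError):
    """Too few data points for the requested fit."""


class FitFailureError(HaksymError, RuntimeError):
    """Nonlinear fit failed to converge or hit a parameter bound."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CalibrationError(HaksymError, RuntimeError):
    """Rate-constant calibration did not reach the requested residual."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FeatureExtractionError(HaksymError, ValueError):
    """A current trace does not cover the protocol windows needed."""


class ParseError(HaksymError, ValueError):
    """A data file could not be parsed.

    Carries the offending file, line and column so tooling can point at the
    exact spot.
    """

    def __init__(self, file: str, line: int | None = None,
                 column: str | int | None = None, reason: str = ""):
        self.file = file
        self.line = line
        self.column = column
        loc = file
        if line is not None:
            loc += f":{line}"
        if column is not None:
            loc += f" (column {column})"
        super().__init__(f"parse error in {loc}: {reason}")
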