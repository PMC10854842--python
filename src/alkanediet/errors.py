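"""Exception hierarchy shared across the package.

Schema problems (a malformed input table) are distinguished from validation
problems (a well-formed table carrying impossible values) and from numerical
failures (solver non-convergence, singular covariance), because the command
line maps them to distinct exit codes.
"""


class AlkaneDietError(Exception):
    """Base class for all package errors."""


class SchemaError(AlkaneDietError):
    """An input table is missing a required column or is otherwise malformed."""


class ValidationError(AlkaneDietError):
    """A value violates a domain invariant (negative concentration, zero intake...)."""


class UndefinedRatioError(ValidationError):
    """A ratio with a zero denominator was requested (percent change from zero)."""


class UndefinedRecoveryError(ValidationError):
    """Recovery is undefined because the dietary marker intake is zero."""


class CorrectionError(ValidationError):
    """A fecal concentration cannot be recovery-corrected (missing/zero entry)."""


class NumericalError(AlkaneDietError):
    """Base class for numerical failures."""


class SolverError(NumericalError):
    """The active-set NNLS solver did not converge.

    Carries the last iterate in ``last_x`` so callers can inspect it.
    """

    def __init__(self, message: str, last_x=None):
        super().__init__(message)
        self.last_x = last_x


class DegenerateModelError(NumericalError):
    """A model fit is degenerate (singular covariance, coincident class means)."""
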