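"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so modules should raise the
most specific class that applies.
"""


class MseSelectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MseSelectError):
    """The analysis specification or config file is invalid."""


class DataError(MseSelectError):
    """The subject-level data violate a precondition (bad outcome code,
    non-positive weight, ...)."""


class DegenerateDesignError(DataError):
    """The requested design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = list(columns or [])


class ConvergenceAbort(MseSelectError):
    """A selection engine had to abort because a required fit failed."""


class GenerationError(MseSelectError):
    """A synthetic scenario is infeasible as parameterized."""
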