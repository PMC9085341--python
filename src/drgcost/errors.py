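"""Exception hierarchy shared across the package."""


class DrgcostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DrgcostError):
    """Invalid configuration: missing columns, bad schema, inconsistent options."""


class InputError(DrgcostError, ValueError):
    """Invalid data handed to an operation (empty group, degenerate factor, ...)."""


class PipelineError(DrgcostError):
    """A pipeline stage cannot proceed (e.g. no records survive cleaning)."""


class ConvergenceError(DrgcostError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class SingularityError(DrgcostError):
    """Degenerate design (constant or collinear column); names the offender."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column
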