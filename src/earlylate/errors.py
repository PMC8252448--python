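"""Exception types shared across the package."""


class EarlyLateError(Exception):
    """Base class for package-specific errors."""


class DegenerateDataError(EarlyLateError):
    """Raised when data carry no residual variation (e.g. a zero-variance arm)."""


class CollinearityError(EarlyLateError):
    """Raised when a regression design matrix is singular."""


class ConvergenceError(EarlyLateError):
    """Raised when an iterative or rejection-based procedure fails to converge."""
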