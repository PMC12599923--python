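"""Exception hierarchy shared across the package."""


class BVarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BVarError, ValueError):
    """An argument violates a documented precondition or invariant."""


class ConfigurationError(ValidationError):
    """A specification object (DGP, pipeline config, ...) is inconsistent."""


class InsufficientDataError(ValidationError):
    """The panel is too short for the requested lag order / holdout."""


class SingularDesignError(BVarError):
    """The lagged regressor matrix is rank deficient."""


class DegenerateInputError(BVarError):
    """A degenerate input (e.g. constant series with zero residual variance)."""


class DecompositionError(BVarError):
    """A matrix factorization (Cholesky) failed, e.g. non-PD covariance."""


class FamilyMismatchError(ValidationError):
    """A prior of the wrong family was passed to a posterior routine."""


class InputError(BVarError):
    """A problem with user-supplied input files (missing column, bad cell)."""
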