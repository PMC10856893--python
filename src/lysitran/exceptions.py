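"""Exception hierarchy shared across the package."""


class LysitranError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LysitranError, ValueError):
    """An argument is outside its documented domain."""


class DomainError(LysitranError, ValueError):
    """A driver value is outside the domain of a model transform (e.g. ln of 0)."""


class AlignmentError(LysitranError, ValueError):
    """Series that must be paired day-by-day do not line up."""


class SchemaError(LysitranError, ValueError):
    """A CSV file does not match its documented schema."""


class MulticollinearityError(LysitranError, ValueError):
    """A design/correlation matrix is singular or numerically rank deficient."""


class FitError(LysitranError, RuntimeError):
    """Nonlinear least squares failed to converge from every start."""
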