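"""Exception hierarchy shared across pipeline stages."""


class FynhydError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(FynhydError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(FynhydError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class AlignmentError(FynhydError, ValueError):
    """Two series that must share a time base do not."""


class DegenerateFitError(FynhydError, ValueError):
    """A regression cannot be fitted (constant predictor, too few points)."""


class FitError(FynhydError, RuntimeError):
    """Nonlinear fit failed to converge after multi-start."""


class StackError(FynhydError, ValueError):
    """An image stack violates its shape/ordering invariants."""


class ExtrapolationError(FynhydError, ValueError):
    """A timestamp falls outside the span of a timeline."""


class IdMismatchError(FynhydError, ValueError):
    """A per-individual mapping was applied to the wrong individual."""


class DependencyError(FynhydError, RuntimeError):
    """A pipeline stage is missing output from an upstream stage."""
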