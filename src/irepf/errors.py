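"""Exception and warning types shared across the package."""


class IrepfError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IrepfError, ValueError):
    """A model parameter violates its physical constraints (e.g. A <= 0)."""


class DegenerateSteepnessError(InvalidParameterError):
    """A survival family evaluates to a non-positive steepness A(x)."""


class DomainError(IrepfError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class InsufficientDataError(IrepfError, ValueError):
    """Too few (or duplicated) data points for the requested fit."""


class UnidentifiableFitError(IrepfError, ValueError):
    """The data cannot identify the model (e.g. all viabilities saturated)."""


class TableFormatError(IrepfError, ValueError):
    """A delimited-text input table violates the expected schema."""


class MeshError(IrepfError, RuntimeError):
    """Mesh construction failed or produced an unusable discretization."""


class ConvergenceError(IrepfError, RuntimeError):
    """An iterative procedure failed to converge.

    Carries the iteration ``history`` (residuals or area records) for
    diagnosis.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history if history is not None else []


class ExtrapolationWarning(UserWarning):
    """A parameter function is evaluated outside its fitted covariate range."""


class IllPosedFitWarning(UserWarning):
    """The fit is formally possible but poorly constrained by the data."""
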