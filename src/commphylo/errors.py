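"""Exception hierarchy shared across the package."""


class CommPhyloError(Exception):
    """Base class for all package errors."""


class ValidationError(CommPhyloError):
    """Invalid input (bad labels, inconsistent constraints, malformed tables)."""


class NewickParseError(ValidationError):
    """Malformed Newick string; message carries the character offset."""


class StateError(CommPhyloError):
    """Operation requires a state the object is not in (e.g. an uncalibrated tree)."""


class DegenerateTraitError(CommPhyloError):
    """Trait has zero variance or too few finite values to fit anything."""


class ConditioningError(CommPhyloError):
    """A covariance matrix is numerically singular (condition number > 1e12)."""


class ConvergenceError(CommPhyloError):
    """Optimizer failed to converge; carries the best fit found so far."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
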