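"""Exception hierarchy.

Fit-level failures are deliberately fine-grained so the selection layer can
skip unfittable candidates instead of ranking them.
"""


class MmlsdmError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MmlsdmError, ValueError):
    """A parameter violates its documented precondition."""


class GeometryError(MmlsdmError, ValueError):
    """Point pattern and grid geometries do not match."""


class DegenerateCovariateError(MmlsdmError, ValueError):
    """A covariate is constant (zero variance) and cannot be standardized."""


class DegenerateDataError(MmlsdmError, ValueError):
    """The response carries no information (empty pattern, all-zero counts,
    constant occupancy)."""


class InsufficientDataError(MmlsdmError, ValueError):
    """Too few observations for the requested fit (e.g. hardcore with < 2
    points)."""


class CollinearityError(MmlsdmError, ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, msg, columns=None):
        super().__init__(msg)
        self.columns = columns or []


class ConvergenceError(MmlsdmError, RuntimeError):
    """Optimizer failed to reach the gradient tolerance within the cap."""


class SeparationError(MmlsdmError, RuntimeError):
    """Complete separation in a logistic fit (coefficients diverge)."""


class DispersionError(MmlsdmError, ValueError):
    """Negative-binomial dispersion estimate is non-positive."""


class SingularInformationError(MmlsdmError, ValueError):
    """Expected Fisher information is singular; message length undefined."""


class NoModelError(MmlsdmError, RuntimeError):
    """Every candidate model in a selection failed to fit."""
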