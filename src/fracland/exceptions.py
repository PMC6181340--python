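"""Named exceptions raised across the package."""


class FraclandError(Exception):
    """Base class for all package errors."""


class DesignError(FraclandError):
    """Invalid design specification or design/covariate mismatch."""


class GridError(FraclandError):
    """Pixel geometry or grid-registration problem."""


class DataError(FraclandError):
    """Invalid or inconsistent input data."""


class EmptyUnitError(DataError):
    """An administrative unit lost all of its pixels."""


class SelectionError(DataError):
    """Unit-selection filter produced an empty sample."""


class EstimationError(FraclandError):
    """Optimisation or variance estimation failure."""


class SeparationError(EstimationError):
    """Parameters diverging without bound (quasi-complete separation)."""


class SingularityError(EstimationError):
    """Singular or ill-conditioned Hessian (collinear design?)."""


class PredictionError(FraclandError):
    """Prediction, scaling or validation input problem."""
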