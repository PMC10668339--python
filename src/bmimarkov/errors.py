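"""Exception hierarchy for bmimarkov."""


class BmiMarkovError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BmiMarkovError, ValueError):
    """A value violates an operation's preconditions (e.g. non-positive BMI)."""


class ConfigurationError(BmiMarkovError, ValueError):
    """A configuration value is inconsistent or refers to missing data."""


class EstimationError(BmiMarkovError):
    """Transition-matrix estimation cannot proceed (e.g. no observed pairs)."""


class ProjectionError(BmiMarkovError):
    """Markov projection failed (singular matrix, non-convergence, ...)."""


class BackwardDistortionError(ProjectionError):
    """Backward projection clipped more probability mass than tolerated.

    Carries the partial trajectory computed before the step that failed.
    """

    def __init__(self, message: str, partial_trajectory=None, distortion: float = 0.0):
        super().__init__(message)
        self.partial_trajectory = partial_trajectory
        self.distortion = distortion


class NotFittedError(BmiMarkovError, RuntimeError):
    """A model was used before being fitted."""
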