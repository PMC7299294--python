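"""Exception types shared across the package."""


class SowlongError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SowlongError):
    """Invalid configuration values (negative counts, fractions outside range, non-PSD covariance)."""


class DataError(SowlongError):
    """Malformed or inconsistent input data (missing covariates, impossible parities, duplicate ids)."""


class PedigreeError(SowlongError):
    """Structural pedigree problems: cycles, offspring before parents, unknown references."""


class NumericalError(SowlongError):
    """Singular or numerically unusable systems (e.g. non-invertible blended genomic matrix)."""


class ConvergenceError(SowlongError):
    """Iterative solver failed to converge; carries the residual history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []
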