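"""Exception hierarchy shared across the package."""


class AedespopError(Exception):
    """Base class for all package-specific errors."""


class InvalidSiteError(AedespopError):
    """Site metadata violates an invariant (latitude range, W* > 0, ...)."""


class InsufficientSeriesError(AedespopError):
    """A time series is too short for the requested operation."""


class WeatherFormatError(AedespopError):
    """A weather or trap-count file failed validation."""


class InvalidCapacityError(AedespopError):
    """Larval carrying capacity is non-positive."""


class NumericalInstabilityError(AedespopError):
    """The integrator produced a non-finite state."""


class CoverageError(AedespopError):
    """Observations fall outside the simulated period."""


class CalibrationError(AedespopError):
    """The annealing sampler could not make progress."""
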