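"""Exception hierarchy for sectorsize.

Every failure mode the library signals deliberately (as opposed to plain
programming errors) derives from :class:`SectorSizeError` so callers can
catch the package's signals in one clause.
"""


class SectorSizeError(Exception):
    """Base class for all sectorsize signals."""


class ParameterError(SectorSizeError, ValueError):
    """Model or noise parameters violate their invariants."""


class DomainError(SectorSizeError, ValueError):
    """An argument lies outside the physically admissible range."""


class ConstraintViolation(SectorSizeError):
    """An integrated state broke a structural constraint (e.g. phi_P < 0)."""


class NoSteadyStateError(SectorSizeError):
    """The fixed-point residual has no root in the search bracket."""


class IntegrationFailure(SectorSizeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class ScheduleError(SectorSizeError, ValueError):
    """An environment schedule is ill-formed (overlapping pulses etc.)."""


class NonIdentifiableError(SectorSizeError):
    """The requested fit is rank deficient for the given data."""


class FitConvergenceError(SectorSizeError):
    """Nonlinear least squares did not converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class CensoredObservation(SectorSizeError):
    """An observable did not occur within the simulated horizon."""

    def __init__(self, message, horizon=None):
        super().__init__(message)
        self.horizon = horizon


class UndefinedObservable(SectorSizeError):
    """The observable is undefined for the given input (e.g. zero variance)."""


class ConfigError(SectorSizeError, ValueError):
    """Scenario configuration failed validation; lists every problem found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid scenario configuration:\n  - " + "\n  - ".join(self.problems))
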