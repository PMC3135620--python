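"""Exception hierarchy."""


class AnoxwaveError(Exception):
    """Base class for all package errors."""


class InvalidStateError(AnoxwaveError, ValueError):
    """A neuron state violates a physical invariant (e.g. negative concentration)."""


class InvalidParameterError(AnoxwaveError, ValueError):
    """A model parameter violates a physical invariant."""


class SolverError(AnoxwaveError, RuntimeError):
    """The ODE solver failed; carries the last good state when available."""

    def __init__(self, message, last_state=None, last_time_s=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time_s = last_time_s


class ConvergenceError(AnoxwaveError, RuntimeError):
    """Resting-state search did not converge; carries the final residual norm."""

    def __init__(self, message, residual_norm=None):
        super().__init__(message)
        self.residual_norm = residual_norm


class ConfigError(AnoxwaveError, ValueError):
    """A run configuration is malformed or violates an invariant."""
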