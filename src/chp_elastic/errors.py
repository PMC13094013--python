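"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class SimulationRangeError(RuntimeError):
    """A simulated compartment fraction left [0, 1]; names the offending time point."""

    def __init__(self, message: str, time_s: float | None = None):
        super().__init__(message)
        self.time_s = time_s


class EmptyPhysioError(RuntimeError):
    """No breaths could be detected in a respiratory trace."""


class ConfigurationError(ValueError):
    """Pipeline inputs are inconsistent (detected before any compute)."""
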