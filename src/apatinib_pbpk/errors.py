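"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An operation was called with arguments outside its domain."""


class ConfigurationError(ValueError):
    """A fixture, scenario file or parameter set is inconsistent."""


class IntegrationFailure(RuntimeError):
    """The ODE integrator failed; carries the time at which it gave up."""

    def __init__(self, message: str, time_of_failure: float | None = None):
        super().__init__(message)
        self.time_of_failure = time_of_failure
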