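"""Exception hierarchy for model parsing, scenarios, simulation and ensembles."""


class AktNfkbError(Exception):
    """Base class for all package errors."""


class ModelSchemaError(AktNfkbError):
    """The model file does not conform to the documented JSON dialect."""


class ModelValidationError(AktNfkbError):
    """A structurally well-formed model violates a semantic invariant."""


class ScenarioError(AktNfkbError):
    """A scenario references ids that do not resolve against the target network."""


class SimulationError(AktNfkbError):
    """The integrator failed; carries the last time it reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class EnsembleError(AktNfkbError):
    """Too many ensemble members failed to integrate."""
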