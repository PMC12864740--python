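"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when user-supplied parameters are out of range or inconsistent."""


class SimulationError(RuntimeError):
    """Raised when the stochastic engine reaches an invalid internal state."""


class EstimationError(RuntimeError):
    """Raised when a mutation-rate estimator is inapplicable to the data."""
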