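"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A structural problem in a network, layout, or stimulus definition."""


class NumericalError(FloatingPointError):
    """Non-finite state encountered during integration."""

    def __init__(self, step: int, neuron: int, message: str = ""):
        self.step = step
        self.neuron = neuron
        super().__init__(
            f"non-finite state at step {step}, neuron {neuron}"
            + (f": {message}" if message else "")
        )


class ProbeError(RuntimeError):
    """Probe readout requested in an invalid network state."""
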