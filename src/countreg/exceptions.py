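"""Package-specific error types."""


class ConfigurationError(ValueError):
    """A generator or workflow configuration is internally inconsistent."""


class SimulationError(RuntimeError):
    """A simulation produced values outside the representable range."""
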