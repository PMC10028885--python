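"""Package exception types."""


class ConfigError(ValueError):
    """Invalid model/network/drive configuration."""


class SimulationError(RuntimeError):
    """Numerical failure during integration (e.g. voltage blow-up)."""
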