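"""Exception types shared across the package."""


class GastromillError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GastromillError, ValueError):
    """A physical parameter is outside its valid domain (e.g. s = 0, C_m <= 0)."""


class ConfigError(GastromillError, ValueError):
    """A circuit configuration failed schema or connectivity validation."""


class IntegrationDivergedError(GastromillError, RuntimeError):
    """Numerical integration produced a non-finite state.

    Carries the compartment name and the simulation time (ms) at which the
    divergence was detected.
    """

    def __init__(self, compartment: str, time_ms: float):
        self.compartment = compartment
        self.time_ms = time_ms
        super().__init__(
            f"integration diverged in compartment {compartment!r} "
            f"at t = {time_ms:.3f} ms"
        )
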