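"""Exception types raised across the package."""


class IcidoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IcidoseError, ValueError):
    """A model or PK parameter violates its constraints."""


class InvalidProtocolError(IcidoseError, ValueError):
    """A dosing protocol violates its constraints."""


class InvalidSettingsError(IcidoseError, ValueError):
    """Simulation settings are inconsistent with the requested analysis."""


class DomainError(IcidoseError, ValueError):
    """A state vector lies outside the model's domain (negative populations)."""


class IntegrationError(IcidoseError, RuntimeError):
    """The ODE solver failed; carries the failing time interval."""

    def __init__(self, message: str, t_span=None):
        super().__init__(message)
        self.t_span = t_span
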