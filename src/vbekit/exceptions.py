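"""Exception types shared across the toolkit."""


class VbeError(Exception):
    """Base class for all vbekit errors."""


class IntegrationError(VbeError):
    """The ODE solver produced a non-finite state."""


class StateViolationError(VbeError):
    """A compartment amount went negative beyond numerical tolerance."""


class InsufficientDataError(VbeError):
    """Not enough observations to compute the requested quantity."""


class ConfigurationError(VbeError):
    """A run configuration is missing or inconsistent."""
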