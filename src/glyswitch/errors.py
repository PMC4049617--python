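"""Exception hierarchy used across the package."""


class GlyswitchError(Exception):
    """Base class for all package errors."""


class DomainError(GlyswitchError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. negative
    concentration)."""


class ConfigurationError(GlyswitchError, ValueError):
    """A model configuration is incomplete or inconsistent (unknown isozyme,
    missing kinetic constant, bad mixture weights...)."""


class NumericalError(GlyswitchError, ArithmeticError):
    """A numerical evaluation produced NaN/Inf or a solver failed."""


class ProtocolError(GlyswitchError, RuntimeError):
    """A simulated experimental protocol cannot be run under the given
    configuration (e.g. pulse protocol requested outside a bistable window)."""
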