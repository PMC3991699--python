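"""Exception hierarchy for pulsemotif."""


class PulseMotifError(Exception):
    """Base class for all pulsemotif errors."""


class InfeasibleSignalError(PulseMotifError, ValueError):
    """A pulse train violates 0 < d <= T, or a protocol cannot produce one."""


class RootNotBracketedError(PulseMotifError, ValueError):
    """A root finder was given a bracket on which the function does not change sign."""


class NumericalDomainError(PulseMotifError, ArithmeticError):
    """A quantity (derivative, rate) evaluated to a non-finite value."""


class InvalidStateError(PulseMotifError, ValueError):
    """A model state violates its conservation laws or bounds."""


class ConvergenceError(PulseMotifError, RuntimeError):
    """Periodic steady state not reached within the allotted number of periods."""

    def __init__(self, message, last_means=None):
        super().__init__(message)
        self.last_means = last_means


class ConfigError(PulseMotifError, ValueError):
    """An experiment configuration failed validation."""
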