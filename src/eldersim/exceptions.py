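"""Exception hierarchy shared across eldersim modules."""


class ElderSimError(Exception):
    """Base class for all eldersim errors."""


class ConfigurationError(ElderSimError):
    """A required signal, parameter block, or config key is missing or malformed."""


class DomainError(ElderSimError):
    """An input is outside the mathematical domain of an operation."""


class AdmissibilityError(DomainError):
    """A parameter combination would produce an inadmissible quantity (e.g. negative cost)."""


class IdentifiabilityError(ElderSimError):
    """Calibration inputs do not determine the parameters (rank-deficient regressors)."""


class SimulationError(ElderSimError):
    """Numerical integration produced a non-finite state."""
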