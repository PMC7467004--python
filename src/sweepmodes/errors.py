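"""Exception hierarchy used across the package."""


class SweepmodesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SweepmodesError):
    """Input data violates a structural or range constraint."""


class ConfigError(SweepmodesError):
    """Run configuration violates a documented constraint."""


class EstimationError(SweepmodesError):
    """A statistical estimate cannot be formed from the data given."""


class ParameterError(SweepmodesError):
    """A model parameter is outside the domain of the approximation."""


class FitError(SweepmodesError):
    """A model fit was requested with an inconsistent context."""
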