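"""Exception hierarchy for the MDD life-course pipeline."""


class MddLifecourseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MddLifecourseError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class EstimationError(MddLifecourseError, RuntimeError):
    """Rate or model estimation failed (empty stratum, separation, no events...)."""


class SimulationError(MddLifecourseError, RuntimeError):
    """The microsimulation engine was asked to do something impossible."""


class UndefinedMediationError(EstimationError):
    """Mediating percentage requested while the total education effect is ~0."""
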