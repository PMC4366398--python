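"""Exception types shared across the package."""


class SanctuaryError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SanctuaryError, ValueError):
    """A model, scenario or config file is internally inconsistent."""


class InvalidGenotypeError(ConfigurationError):
    """A genotype's mutation cost drives its birth rate to zero or below."""


class ConvergenceError(SanctuaryError, RuntimeError):
    """A numerical routine failed to reach its tolerance.

    Carries the last iterate so callers can inspect how far the
    computation got.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NullConditioningError(SanctuaryError, ValueError):
    """Conditioning event (eventual resistance) has zero probability."""
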