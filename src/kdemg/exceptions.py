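"""Exception hierarchy shared across the package."""


class KdemgError(Exception):
    """Base class for all package errors."""


class InvalidBandError(KdemgError):
    """Filter band edges outside (0, fs/2) or inverted."""


class TooShortError(KdemgError):
    """Signal or sequence shorter than the operation requires."""


class DegenerateChannelError(KdemgError):
    """A channel with zero variance where spread is required."""


class DegenerateSampleError(KdemgError):
    """Sample vector with zero spread handed to a density estimator."""


class InvalidBandwidthError(KdemgError):
    """Non-positive kernel bandwidth."""


class InvalidOrderError(KdemgError):
    """Negative derivative order."""


class EmptyInputError(KdemgError):
    """Empty vector where at least one value is required."""


class SchemaError(KdemgError):
    """Inconsistent record collection (channel counts, sampling rates)."""


class StratificationError(KdemgError):
    """A class has too few rows for the requested stratified procedure."""


class ConfigError(KdemgError):
    """Invalid experiment or generator configuration."""
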