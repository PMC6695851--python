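"""Exception hierarchy shared by all avfppg modules."""


class AvfPpgError(Exception):
    """Base class for all package errors."""


class DomainError(AvfPpgError, ValueError):
    """An argument violates a physical or mathematical precondition."""


class ConfigError(AvfPpgError, ValueError):
    """Invalid configuration file or parameter set."""


class DataError(AvfPpgError, ValueError):
    """Malformed or insufficient input data."""


class EstimationError(DataError):
    """A signal-derived quantity (heart rate, beats) could not be estimated."""


class InsufficientSignalError(EstimationError):
    """Too few valid beats to extract features."""


class GenerationError(AvfPpgError, RuntimeError):
    """Synthetic cohort generation could not satisfy the requested spec."""


class TrainingError(AvfPpgError, RuntimeError):
    """A classifier failed to train (e.g. QP solver non-convergence)."""
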