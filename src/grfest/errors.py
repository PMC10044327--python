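"""Exception hierarchy for the grfest pipeline."""


class GrfestError(Exception):
    """Base class for all grfest errors."""


class ConfigurationError(GrfestError):
    """Invalid configuration value (bad motion type, cutoff >= Nyquist, ...)."""


class DataError(GrfestError):
    """Malformed or inconsistent session data (missing channel, ragged lengths)."""


class ModelError(GrfestError):
    """Model misuse (dimension mismatch vs. trained pattern, unfitted decoder)."""


class TrainingDivergedError(GrfestError):
    """Training loss became non-finite."""
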