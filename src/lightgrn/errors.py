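"""Package-specific exceptions."""


class LightGRNError(Exception):
    """Base class for all package errors."""


class GridError(LightGRNError):
    """Invalid or incompatible time grid."""


class AlignmentError(LightGRNError):
    """Profiles expected on the same uniform grid are not aligned."""


class MissingProfileError(LightGRNError):
    """A required expression profile is absent."""


class CapacityError(LightGRNError):
    """A request exceeds what the inputs can supply (e.g. too many decoys)."""


class UndefinedCorrelationError(LightGRNError):
    """Pearson correlation undefined because a profile has zero variance."""


class SingularityError(LightGRNError):
    """Rank-deficient regression design."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class IdentifiabilityError(LightGRNError):
    """Fewer observations than parameters."""


class ConfigError(LightGRNError):
    """Invalid pipeline configuration."""
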