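"""Exception hierarchy for the protreact package."""


class ProtReactError(Exception):
    """Base class for all package-specific errors."""


class DatasetError(ProtReactError):
    """Raised when the chemicals table cannot be parsed or violates its schema."""


class InvalidRunError(ProtReactError):
    """Raised for a plate run with no usable dynamic range (A <= B) or failed QC."""


class InsufficientReplicationError(ProtReactError):
    """Raised when fewer independent runs are available than the required minimum."""


class DegenerateDataError(ProtReactError):
    """Raised when ROC analysis is attempted on single-class input."""


class ConfigurationError(ProtReactError):
    """Raised when a prediction-model configuration is inconsistent with its inputs."""
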