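"""Exception types shared across the pipeline."""


class BeakFusionError(Exception):
    """Base class for all package-specific errors."""


class ImageDecodeError(BeakFusionError):
    """Raised when an image file cannot be read or decoded."""


class ImageFormatError(BeakFusionError):
    """Raised for unsupported image formats or bit depths."""


class SizeError(BeakFusionError):
    """Raised when an image or grid does not meet a size precondition."""


class SplitSizeError(BeakFusionError):
    """Raised when a class has too few samples to be split."""


class ParameterError(BeakFusionError):
    """Raised for invalid transform or descriptor parameters."""


class PairingError(BeakFusionError):
    """Raised when two feature vectors to be fused disagree on provenance."""


class ShapeError(BeakFusionError):
    """Raised for feature-length mismatches between fit and predict."""


class DegenerateLabelError(BeakFusionError):
    """Raised when training labels contain fewer than two classes."""


class LabelError(BeakFusionError):
    """Raised when a label is outside the declared class set."""


class DataError(BeakFusionError):
    """Raised for empty or otherwise unusable data."""


class ConfigError(BeakFusionError):
    """Raised for invalid configuration values."""


class StageOrderError(BeakFusionError):
    """Raised when a pipeline stage runs before its prerequisites exist."""


class ProvenanceError(BeakFusionError):
    """Raised when artifacts from incompatible pipeline runs are combined."""
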