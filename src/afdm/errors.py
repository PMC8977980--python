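"""Exception types shared across the package."""


class AfdmError(Exception):
    """Base class for package errors."""


class MissingInputError(AfdmError, FileNotFoundError):
    """A required file or directory is absent."""


class SchemaError(AfdmError, ValueError):
    """An artifact's structure does not match its contract."""


class DataError(AfdmError, ValueError):
    """Samples are malformed (NaN, wrong length, ...)."""


class InvalidParameterError(AfdmError, ValueError):
    """A configuration value is out of its admissible range."""


class UndefinedDclError(AfdmError, ValueError):
    """Too few activations to estimate a dominant cycle length."""


class UndefinedBurdenError(AfdmError, ValueError):
    """No bipolar channel produced a usable burden score."""


class UndefinedMetricError(AfdmError, ValueError):
    """A map metric is requested with no observed vertices."""


class SegmentationError(AfdmError, ValueError):
    """A landmark required for regional segmentation is missing."""


class ClassificationError(AfdmError, ValueError):
    """Driver-location classification is impossible (e.g. open line)."""


class SeparationError(AfdmError, ValueError):
    """Complete separation in a logistic fit; use the penalized mode."""
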