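"""Exception hierarchy shared across the pipeline."""


class CardioCSError(Exception):
    """Base class for all package errors."""


class ParameterError(CardioCSError, ValueError):
    """An argument is outside its documented domain."""


class DataError(CardioCSError, ValueError):
    """Input data violates a structural precondition (empty corpus, tiny class...)."""


class FormatError(CardioCSError, ValueError):
    """A file does not conform to the delimited-text signal/dictionary format."""


class DetectionError(CardioCSError, RuntimeError):
    """Fiducial detection failed (e.g. no R peak found)."""


class UndefinedMetricError(CardioCSError, ValueError):
    """A quality metric is undefined for this input (e.g. zero reference signal)."""


class ConfigurationError(CardioCSError, ValueError):
    """An experiment or solver configuration cannot be satisfied."""
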