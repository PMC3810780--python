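"""Exception hierarchy shared across the pipeline."""


class FemdriftError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FemdriftError, ValueError):
    """A gaze table is malformed (missing columns, bad header, ...)."""


class SamplingError(FemdriftError, ValueError):
    """Timestamps deviate from the declared uniform sampling grid."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class TooShortError(FemdriftError, ValueError):
    """An input series is too short for the requested operation."""


class InsufficientDataError(FemdriftError, ValueError):
    """Not enough observations to fit or summarize."""


class ParameterError(FemdriftError, ValueError):
    """An invalid model or configuration parameter."""


class GeneratorError(FemdriftError, ValueError):
    """A synthetic event cannot be rendered with detectable properties."""


class IncompleteTableError(FemdriftError, RuntimeError):
    """A lookup table is missing entries and cannot be used for fitting."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = missing or []
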