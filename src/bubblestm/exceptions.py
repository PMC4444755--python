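"""Package-specific error types."""


class BubbleSTMError(Exception):
    """Base class for all bubblestm errors."""


class InvalidConfigurationError(BubbleSTMError):
    """An analysis parameter combination is internally inconsistent."""


class InsufficientDataError(BubbleSTMError):
    """Too few frames / presentations to run the requested analysis."""


class NoReceptiveFieldError(BubbleSTMError):
    """The probe response map carries no spatial structure to fit."""


class EmptyResponseError(BubbleSTMError):
    """All frame responses are zero; a rate-weighted average is undefined."""
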