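"""Exception hierarchy for eegdx."""


class EegdxError(Exception):
    """Base class for all eegdx errors."""


class ConfigurationError(EegdxError):
    """A parameter or specification object is invalid; the message names the field."""


class ChannelError(EegdxError):
    """Channel labels missing, unknown, or inconsistent across recordings."""


class SignalTooShortError(EegdxError):
    """Input signal shorter than an operation's minimum length."""


class DegenerateInputError(EegdxError):
    """Input is degenerate for the requested operation (e.g. all-zero spectrum)."""


class PipelineStageError(EegdxError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
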