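"""Exception hierarchy for the inkms package."""


class InkmsError(Exception):
    """Base class for all inkms errors."""


class ValidationError(InkmsError):
    """Invalid parameter, metadata or input contract violation."""


class ParseError(ValidationError):
    """A file could not be parsed; message carries the offending line."""


class PipelineError(InkmsError):
    """A pipeline stage failed at run time."""
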