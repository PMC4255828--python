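"""Exception hierarchy shared across the pipeline stages."""


class EmbryoScreenError(Exception):
    """Base class for all data / configuration errors raised by this package."""


class ValidationError(EmbryoScreenError):
    """A value violated a documented invariant (names the offending field)."""


class FormatError(EmbryoScreenError):
    """A file could not be parsed; carries file/record coordinates."""
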