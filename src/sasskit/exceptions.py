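"""Structured exceptions raised across the toolkit."""


class SasskitError(Exception):
    """Base class for all toolkit errors."""


class FileFormatError(SasskitError):
    """A file is missing, malformed, or uses an unsupported dialect.

    Attributes
    ----------
    path : str | None
        Offending file, when known.
    keyword : str | None
        Offending format keyword, when the problem is an unsupported dialect.
    """

    def __init__(self, message, *, path=None, keyword=None):
        super().__init__(message)
        self.path = path
        self.keyword = keyword


class DataRangeError(SasskitError):
    """Sample values exceed the representable range of the chosen encoding."""


class DegenerateDataError(SasskitError):
    """Input data carry no usable information (zero variance, too few events, ...)."""


class ChannelMismatchError(SasskitError):
    """Channel sets or channel order differ between objects that must align."""
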