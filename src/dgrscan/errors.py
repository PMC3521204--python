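"""Exception types shared across the package."""


class DgrScanError(Exception):
    """Base class for all package errors."""


class InputError(DgrScanError):
    """Unreadable input, bad argument, or unusable value."""


class ParseError(DgrScanError):
    """A record or table could not be parsed; the message names the culprit."""


class CoordinateError(DgrScanError):
    """An interval falls outside its parent sequence or region."""


class SizingError(DgrScanError):
    """A synthetic-genome spec does not fit into the requested contig length."""
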