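"""Exception hierarchy shared across the package."""


class FlagmetError(Exception):
    """Base class for all domain errors raised by flagmet."""


class ParseError(FlagmetError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FlagmetError):
    """An in-memory object violates one of its invariants."""


class InsufficientMarkerSignalError(FlagmetError):
    """Raised when the single-copy marker gene median RPK is zero.

    A metagenome with no marker-gene signal cannot be normalized, so the
    flagellar motility index is undefined for it.
    """
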