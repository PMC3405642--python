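"""Exception hierarchy shared across the package."""


class MitomatchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MitomatchError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MitomatchError):
    """Parsed content violates a domain invariant."""
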