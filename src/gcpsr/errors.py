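"""Exception hierarchy shared across the pipeline stages."""


class GcpsrError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GcpsrError, ValueError):
    """Input violates a documented precondition or invariant."""


class AlignmentError(ValidationError):
    """Rows of a would-be alignment are inconsistent (e.g. ragged lengths)."""


class FormatError(GcpsrError, ValueError):
    """A file or text blob cannot be parsed in the expected format."""
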