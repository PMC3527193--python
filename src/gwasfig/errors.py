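"""Exception hierarchy for gwasfig.

All package errors derive from :class:`GwasFigError` so CLI code can catch
one type and turn it into a one-line diagnostic with a nonzero exit code.
"""


class GwasFigError(Exception):
    """Base class for all gwasfig errors."""


class FormatError(GwasFigError):
    """Structurally malformed input (too few columns, bad header)."""


class TraitCapError(FormatError):
    """More than the supported maximum of 100 trait columns."""


class ParseError(GwasFigError):
    """A data line failed to parse; message carries the line number."""


class ValidationError(GwasFigError):
    """Parsed values violate a domain constraint (e.g. P outside [0, 1])."""


class MappingError(GwasFigError):
    """A column map references a column outside the file's column range."""


class LookupError_(GwasFigError):
    """A requested trait or chromosome does not exist."""


class OptionError(GwasFigError):
    """An unsupported option value (format, sort key, ...)."""


class EmptyInputError(GwasFigError):
    """An operation received no usable (non-missing) data."""
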