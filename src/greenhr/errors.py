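"""Exception hierarchy for greenhr.

All package errors derive from :class:`GreenHRError` so callers can catch
one base class.  ``ValidationError`` covers bad values (out-of-range bpm,
inconsistent arguments), ``ParseError`` covers malformed input files, and
``InsufficientDataError`` covers series too short for an operation.
"""


class GreenHRError(Exception):
    """Base class for all greenhr errors."""


class ValidationError(GreenHRError, ValueError):
    """A value violates a domain invariant (e.g. bpm outside (0, 300))."""


class ParseError(GreenHRError, ValueError):
    """An input file could not be parsed; the message names the line."""


class InsufficientDataError(GreenHRError, ValueError):
    """A series has too few samples for the requested operation."""
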