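"""Exception hierarchy.

All package errors derive from :class:`BioGPSError` so callers can catch one
type; each also derives from the closest builtin (ValueError) so that code
written against plain numpy/pandas conventions keeps working.
"""


class BioGPSError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(BioGPSError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ShapeError(BioGPSError, ValueError):
    """Dimension mismatch between admixture vectors / frequency matrices."""


class DomainError(BioGPSError, ValueError):
    """A scalar argument outside its mathematical domain (e.g. lat > 90)."""


class InputError(BioGPSError, ValueError):
    """Semantically invalid input data (empty panel, unknown label, ...)."""


class ParseError(BioGPSError, ValueError):
    """Malformed input file; includes the offending line number when known."""
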