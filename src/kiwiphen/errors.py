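"""Exceptions shared across the pipeline."""


class KiwiphenError(Exception):
    """Base class for package errors."""


class UndefinedResult(KiwiphenError):
    """A quantity is mathematically undefined for this input.

    Raised instead of returning a sentinel (0, 1, NaN) so callers must
    decide explicitly how to handle empty masks, zero denominators, etc.
    """


class FormatError(KiwiphenError):
    """Input raster or table does not have the required layout."""


class DesignError(KiwiphenError):
    """Experimental design is incomplete for the requested computation
    (missing view, empty factor cell, absent effect entry)."""
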