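"""Exception hierarchy.

``ParameterError`` flags an invalid analysis parameter (window size, model
parameter out of range); ``InputError`` flags data that cannot be processed
(wrong shape, too few exposures).  Both derive from :class:`ValueError` so
generic callers can catch either.
"""


class FiberMESIError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FiberMESIError, ValueError):
    """An analysis parameter is invalid (e.g. even window, nonpositive time)."""


class InputError(FiberMESIError, ValueError):
    """Input data is unusable (shape mismatch, too few samples, bad stack)."""


class FormatError(FiberMESIError, ValueError):
    """A file on disk does not match the expected layout."""


class SegmentationError(FiberMESIError, RuntimeError):
    """Fiber segmentation failed (e.g. no circular cores detected)."""
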