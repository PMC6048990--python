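"""Exception hierarchy shared across the toolkit."""


class ScratchkinError(Exception):
    """Base class for all toolkit errors."""


class IndexFormatError(ScratchkinError, ValueError):
    """Index file is malformed (missing column, unparseable field)."""


class ValidationError(ScratchkinError, ValueError):
    """Input violates a documented contract (shapes, duplicates, ranges)."""


class DegenerateInputError(ScratchkinError, ValueError):
    """Input is formally valid but carries no usable signal
    (constant image, zero-variance observations, all-zero series)."""


class ScratchDetectionError(ScratchkinError, RuntimeError):
    """No cell-free area could be found in the positional histogram."""
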