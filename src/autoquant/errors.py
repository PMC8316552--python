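"""Exception hierarchy shared by all pipeline stages."""


class AutoquantError(Exception):
    """Base class for all package errors."""


class ParameterError(AutoquantError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(AutoquantError, IOError):
    """An input file is unreadable or has ambiguous layout."""


class SegmentationError(AutoquantError):
    """Segmentation produced no usable mask."""


class PartitionError(AutoquantError):
    """The equal-area ring solver could not reach the requested tolerance."""


class ProfileError(AutoquantError):
    """A radial profile could not be computed (e.g. zero total intensity)."""


class InputError(AutoquantError, ValueError):
    """A table or data structure is missing required content."""
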