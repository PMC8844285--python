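"""Exception hierarchy shared across the package."""


class MtpefError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MtpefError, ValueError):
    """A numeric parameter is outside its physical domain."""


class InvalidInputError(MtpefError, ValueError):
    """Input data violates a precondition (shapes, ordering, emptiness)."""


class InvalidProtocolError(MtpefError, ValueError):
    """Pulse protocols are malformed or overlap in time."""


class DegenerateBackgroundError(MtpefError, ValueError):
    """Background region has zero (or non-positive) mean intensity."""


class UndefinedOverlapRateError(MtpefError, ValueError):
    """MOR denominator has no supra-threshold pixels."""


class EventWindowError(MtpefError, ValueError):
    """A pulse-train event falls outside the recorded frame times."""


class StackFormatError(MtpefError, IOError):
    """An image stack on disk is corrupt, truncated or unsupported."""
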