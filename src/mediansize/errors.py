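"""Exception types raised by the calculator and simulation engine."""


class MedianSizeError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(MedianSizeError):
    """A design parameter is outside its admissible range."""


class NoDetectableDifferenceError(MedianSizeError):
    """The specified medians are equal: the log-median difference is zero
    and the required sample size is infinite."""


class DegenerateDesignError(MedianSizeError):
    """Both groups have zero variance: no sampling variability to power
    a test against."""
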