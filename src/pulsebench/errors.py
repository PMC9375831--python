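"""Exception hierarchy shared across the toolkit."""


class PulsebenchError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgument(PulsebenchError, ValueError):
    """A parameter is outside its allowed domain."""


class TooShortSignal(PulsebenchError):
    """The signal is too short for the requested operation."""


class InsufficientPeaks(PulsebenchError):
    """Fewer usable pulsatile peaks than the operation requires."""


class InsufficientData(PulsebenchError):
    """Not enough observations/intervals to compute the quantity."""


class DegenerateSignal(PulsebenchError):
    """Signal has no usable structure (zero power, constant, flat)."""


class DegenerateSeries(PulsebenchError):
    """Series has zero variance where variability is required."""


class UndefinedMetric(PulsebenchError):
    """A ratio metric whose denominator is zero."""


class FlatSignal(DegenerateSignal):
    """All analysis windows were degenerate (e.g. constant video)."""


class InvalidLabel(PulsebenchError, ValueError):
    """Unknown task or group code in a manifest row."""


class InvalidSplit(PulsebenchError):
    """A train/test partition ended up single-class."""
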