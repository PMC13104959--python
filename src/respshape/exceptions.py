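"""Exception hierarchy for respshape.

All package errors derive from :class:`RespShapeError`, so callers can catch
one base class. The leaf classes mirror the failure modes of the pipeline:
bad arguments, impossible configurations, and signals that are degenerate for
a given analysis stage.
"""


class RespShapeError(Exception):
    """Base class for all respshape errors."""


class InvalidArgumentError(RespShapeError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(RespShapeError, ValueError):
    """A run configuration is internally contradictory or unusable."""


class DegenerateSignalError(RespShapeError):
    """The signal is degenerate for the requested operation (e.g. constant)."""


class NoBreathingPeakError(RespShapeError):
    """No periodic peak found in the respiration spectrum; participant excluded."""


class EmptyExtremaError(RespShapeError):
    """Extrema detection or cycle rejection left no usable extrema."""


class InsufficientDataError(RespShapeError):
    """Too few epochs/cycles/participants for the requested statistic."""


class EmptyEpochsError(InsufficientDataError):
    """No usable respiration-peak-centered epochs could be formed."""


class MarginTooLargeError(ConfigurationError):
    """Permutation margin leaves no legal sampling region."""
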