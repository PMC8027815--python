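"""Exception hierarchy.

All package errors derive from :class:`TissueCondError` so callers can catch
one base class; subclasses map to the pipeline stage that raised them and to
the CLI exit codes (config/validation -> 2, parse -> 3, analysis QC -> 4).
"""


class TissueCondError(Exception):
    """Base class for all errors raised by tissuecond."""


class GeometryError(TissueCondError, ValueError):
    """Invalid sample geometry (non-positive radius or thickness)."""


class DomainError(TissueCondError, ValueError):
    """An argument is outside its physical domain (e.g. negative voltage)."""


class ConfigError(TissueCondError, ValueError):
    """Invalid run configuration or scenario specification."""


class ParseError(TissueCondError, ValueError):
    """A data file could not be parsed as the expected CSV schema."""


class SamplingError(TissueCondError, ValueError):
    """Sampling rate too low to resolve the requested pulse shape."""


class InvalidRecordingError(TissueCondError, ValueError):
    """A recording violates its invariants (non-uniform time base, ...)."""


class ConditioningError(TissueCondError, ValueError):
    """DC-offset removal asked to use a quiet window that is not quiet."""


class FilterDesignError(TissueCondError, ValueError):
    """Butterworth cutoff at or above the Nyquist frequency."""


class SegmentationError(TissueCondError, ValueError):
    """Pulse segmentation produced an unusable window."""


class ProtocolMismatchError(TissueCondError, ValueError):
    """Detected pulse count disagrees with the declared protocol."""


class MeasurementError(TissueCondError, ValueError):
    """A conductivity measurement is unphysical (non-positive current...)."""


class AggregationError(TissueCondError, ValueError):
    """Curve assembly is missing required pairings (e.g. no baseline)."""


class InvalidSpectrumError(TissueCondError, ValueError):
    """An impedance spectrum violates its invariants."""


class ExtrapolationError(TissueCondError, ValueError):
    """A frequency query falls outside the measured range."""


class DegenerateVarianceError(TissueCondError, ValueError):
    """Welch test requested with n < 2 or zero variance."""
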