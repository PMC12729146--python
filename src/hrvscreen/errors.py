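"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`HRVScreenError` so callers can halt a
run with the stage name and the offending record attached.
"""


class HRVScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(HRVScreenError, ValueError):
    """Non-finite or out-of-range generator/filter parameter."""


class ConfigurationError(HRVScreenError, ValueError):
    """Invalid or incomplete run configuration (e.g. a missing effect profile)."""


class ResolutionError(HRVScreenError, ValueError):
    """Sampling rate too low to represent the requested waveform or filter edge."""


class DetectionError(HRVScreenError, RuntimeError):
    """R-peak detection failed (flat signal, fewer than two beats, ...)."""


class SegmentError(HRVScreenError, ValueError):
    """Malformed stimulus segment annotation (start >= end, overlap, ...)."""


class InsufficientDataError(HRVScreenError, ValueError):
    """Too few NN intervals / epochs for the named quantity."""

    def __init__(self, feature: str, message: str):
        self.feature = feature
        super().__init__(f"{feature}: {message}")


class UndefinedFeatureError(HRVScreenError, ValueError):
    """A feature is mathematically undefined on this input (e.g. LF/HF with HF=0)."""


class OutOfBandError(HRVScreenError, ValueError):
    """Spectral peak falls outside the physiological band."""


class BaselineDegenerateError(HRVScreenError, ValueError):
    """Calm baseline cannot be fitted (fewer than two calm epochs)."""


class KeyingError(HRVScreenError, ValueError):
    """Participant id mismatch between a feature vector and a baseline."""


class IncompleteDesignError(HRVScreenError, ValueError):
    """A (group, condition) cell required by the screen is missing or too small."""


class StratificationError(HRVScreenError, ValueError):
    """Train/test split impossible (a class is absent)."""


class UndefinedMetricError(HRVScreenError, ValueError):
    """A classification metric is undefined (e.g. AUC on a one-class test set)."""


class ValidationError(HRVScreenError, ValueError):
    """Input table fails validation (e.g. PHQ-9 score outside 0-27)."""
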