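"""Exception hierarchy for the lumbargait package."""


class LumbarGaitError(Exception):
    """Base class for all lumbargait errors."""


class FormatError(LumbarGaitError):
    """A file does not have the expected columns/datasets."""


class ValidationError(LumbarGaitError):
    """Data violate an invariant (non-monotone time, long NaN runs, ...)."""


class ParameterError(LumbarGaitError):
    """A parameter value is inconsistent (band edges vs. Nyquist, even
    Savitzky-Golay frame, segment shorter than a filter frame, ...)."""


class SegmentTooShortError(ParameterError):
    """A walking segment is too short for the event filter cascade; the
    pipeline skips such segments instead of failing."""


class ConfigError(LumbarGaitError):
    """A configuration file or simulation config is inconsistent."""


class EstimationError(LumbarGaitError):
    """A statistical estimate is undefined on the given input."""


class TuningError(LumbarGaitError):
    """Brute-force filter tuning found no usable grid point."""
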