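"""Exception hierarchy for the gaitdx pipeline."""


class GaitdxError(Exception):
    """Base class for all gaitdx errors."""


class ConfigurationError(GaitdxError):
    """Invalid configuration value (counts, durations, cutoffs, thresholds)."""


class SegmentTooShortError(GaitdxError):
    """Signal segment too short for the requested operation."""


class NormalizationError(GaitdxError):
    """Segment cannot be mean-normalized (zero mean)."""


class UndefinedFeatureError(GaitdxError):
    """Feature is mathematically undefined on this segment (e.g. all-zero input)."""


class RankingError(GaitdxError):
    """Feature ranking cannot proceed (e.g. single-class labels)."""


class ParameterError(GaitdxError):
    """Algorithm parameter incompatible with the data (e.g. k exceeds class size)."""


class LeakageError(GaitdxError):
    """Machine-checked train/test contamination in cross-validation."""
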