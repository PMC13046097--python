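"""Exception hierarchy for the validation pipeline.

Every stage raises a subclass of :class:`HypnovalError` so that the
pipeline driver can attach stage and subject context before re-raising.
"""


class HypnovalError(Exception):
    """Base class for all package errors."""


class FormatError(HypnovalError):
    """A file does not conform to the declared dialect (bad header, row, label)."""


class ContiguityError(FormatError):
    """Gap or overlap between consecutive epochs of a hypnogram file."""


class GridError(HypnovalError):
    """Epoch grids are incompatible (non-uniform, non-divisible, mis-snapped)."""


class MappingError(HypnovalError):
    """A stage relabeling table does not cover the source vocabulary."""


class VocabularyError(HypnovalError):
    """A stage label or vocabulary does not match what an operation requires."""


class WindowError(HypnovalError):
    """An analysis window does not intersect the data it is applied to."""


class AlignmentError(HypnovalError):
    """Two hypnograms share no usable temporal overlap or disagree on the grid."""


class EmptyNightError(HypnovalError):
    """No valid epochs remain for a night after masking."""


class DataError(HypnovalError):
    """Signal data insufficient for the requested analysis (e.g. short overlap)."""


class DegenerateSignalError(DataError):
    """A zero-variance signal cannot be correlated."""


class SampleSizeError(HypnovalError):
    """Too few paired observations for the requested statistic."""


class FitError(HypnovalError):
    """A regression fit is degenerate (e.g. all points coincident)."""


class GroupingError(HypnovalError):
    """A subgroup is empty or a grouping column is missing."""


class StratumError(HypnovalError):
    """A stratified comparison received an empty stratum."""


class ConfigError(HypnovalError):
    """Invalid pipeline or simulation configuration."""
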