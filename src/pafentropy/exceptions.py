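"""Exception hierarchy for the PAF-entropy pipeline.

Every stage raises a subclass of :class:`PafError` so callers (and the CLI)
can tag failures by stage without string matching.
"""


class PafError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(PafError, ValueError):
    """A configuration value violates an operation's precondition."""


class TooShortSignalError(PafError):
    """Input signal is too short for the requested operation."""


class UnsupportedRateError(PafError):
    """Sampling rate outside the range the algorithm supports."""


class NoPeaksError(PafError):
    """QRS detection found no peaks (e.g. flat-line input)."""


class InsufficientDataError(PafError):
    """Too few beats/intervals/samples for the computation."""


class EmptySeriesError(PafError):
    """Artifact cleaning removed every interval."""


class DegenerateLevelError(PafError):
    """A wavelet level carries zero energy; no distribution exists."""


class UndefinedEntropyError(PafError):
    """Sample entropy undefined (no template matches)."""


class DegenerateTrainingError(PafError):
    """Classifier training data contains a single class."""
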