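"""Exception hierarchy for gaitmet.

All errors derive from :class:`GaitmetError` so callers can catch the
package's failures with a single except clause; most also derive from the
matching builtin (ValueError / RuntimeError) for idiomatic handling.
"""


class GaitmetError(Exception):
    """Base class for all gaitmet errors."""


class InvalidDesignError(GaitmetError, ValueError):
    """A cohort design parameter is out of its admissible range."""


class TooShortSeriesError(GaitmetError, ValueError):
    """A time series is too short to resample (needs >= 2 samples)."""


class InvalidDataError(GaitmetError, ValueError):
    """Input data contain non-finite or otherwise invalid values."""


class InvalidMassError(GaitmetError, ValueError):
    """Body mass must be strictly positive."""


class NoDataError(GaitmetError, ValueError):
    """An operation received an empty collection of trials/strides."""


class ShapeError(GaitmetError, ValueError):
    """Array shapes are inconsistent with each other or with a model."""


class TooFewTrialsError(GaitmetError, ValueError):
    """Not enough trials to build the requested partition."""


class InvalidConfigError(GaitmetError, ValueError):
    """A network or search configuration is internally inconsistent."""


class NotFittedError(GaitmetError, RuntimeError):
    """A model was used for prediction before being trained."""


class ConvergenceError(GaitmetError, RuntimeError):
    """The Levenberg-Marquardt damping exceeded its ceiling."""


class UndefinedMetricError(GaitmetError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""


class ChannelMismatchError(GaitmetError, ValueError):
    """A requested waveform channel is not an input of the model."""


class FormatError(GaitmetError, ValueError):
    """A CSV/JSON/YAML artifact does not match the expected schema."""
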