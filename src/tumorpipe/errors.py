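"""Typed exceptions shared across the pipeline.

Every contract violation raises a distinct subclass of :class:`TumorPipeError`
so callers (and the CLI) can map failures to stable messages and exit codes
instead of pattern-matching on strings.
"""


class TumorPipeError(Exception):
    """Base class for all package errors."""


class OutOfRangeError(TumorPipeError):
    """A pixel or level value falls outside the declared gray-level range."""


class DegenerateInputError(TumorPipeError):
    """An input is empty or otherwise carries no usable information."""


class InfeasibleClipError(TumorPipeError):
    """Histogram mass cannot fit under the requested clip ceiling."""


class ConfigurationError(TumorPipeError):
    """A configuration value is inconsistent or unusable."""


class NoValidSplitError(TumorPipeError):
    """Otsu thresholding needs at least two occupied gray levels."""


class SchemaError(TumorPipeError):
    """Shapes, lengths or feature names of two objects do not line up."""


class UndefinedSimilarityError(TumorPipeError):
    """The max-min similarity is undefined (both vectors all zero)."""


class UndefinedMetricError(TumorPipeError):
    """A confusion-matrix metric has an empty denominator."""


class DataError(TumorPipeError):
    """A dataset violates a training precondition (e.g. an empty class)."""


class PhantomSpecError(TumorPipeError):
    """A phantom specification is geometrically or numerically invalid."""
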