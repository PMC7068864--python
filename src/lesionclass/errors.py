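"""Exception hierarchy shared across the lesionclass pipeline.

Every stage raises a subclass of :class:`LesionClassError` so that the
orchestration layer can report which stage failed without string matching.
"""


class LesionClassError(Exception):
    """Base class for all lesionclass errors."""


class ParameterError(LesionClassError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(LesionClassError, ValueError):
    """Input raster has the wrong number of channels / dtype / range."""


class DimensionError(LesionClassError, ValueError):
    """Vector or table length does not match the expected dimension."""


class EmptyROIError(LesionClassError, ValueError):
    """An operation that needs a non-empty lesion mask received none."""


class DegenerateShapeError(LesionClassError, ValueError):
    """Mask geometry is degenerate (e.g. collinear pixels)."""


class DegenerateTrainingError(LesionClassError, ValueError):
    """Training data cannot support fitting (e.g. a single class)."""


class MetricUndefinedError(LesionClassError, ZeroDivisionError):
    """A requested metric has a zero denominator for these counts."""


class StateError(LesionClassError, RuntimeError):
    """Operation requires state (e.g. a trained network) that is absent."""


class StageError(LesionClassError, RuntimeError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
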