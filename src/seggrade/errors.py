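"""Exception hierarchy for the seggrade pipeline."""


class SegGradeError(Exception):
    """Base class for all seggrade errors."""


class EmptyClassError(SegGradeError):
    """Requested label class has no pixels in the mask."""


class DegenerateGeometryError(SegGradeError):
    """Mask foreground is empty, a single pixel, or collinear: no rectangle exists."""


class UndefinedMetricError(SegGradeError):
    """A metric denominator is zero (empty class, empty confusion matrix)."""


class InvalidCriteriaError(SegGradeError):
    """Grade intervals overlap, leave gaps, or are not increasing."""


class OutOfCanvasError(SegGradeError):
    """A rendered fixture would clip the canvas boundary."""


class MultipleInstancesError(SegGradeError):
    """More than one mushroom detected in a single frame."""


class ConfigError(SegGradeError):
    """Pipeline configuration failed validation."""
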