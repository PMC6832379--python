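"""Exception hierarchy for the measurement pipeline."""


class FemurBowError(Exception):
    """Base class for all femurbow errors."""


class InvalidPolylineError(FemurBowError, ValueError):
    """A polyline has fewer than 2 points, non-finite or repeated vertices."""


class ParameterError(FemurBowError, ValueError):
    """An operation parameter is out of its valid range."""


class LandmarkConstructionError(FemurBowError):
    """An anatomical endpoint could not be constructed from the annotation."""


class TopologyError(FemurBowError):
    """The two borders intersect or bound a degenerate (zero-width) domain."""


class ExtractionError(FemurBowError):
    """The territory meeting locus could not be chained into one midline."""


class StraightSegmentError(FemurBowError):
    """Points are collinear; no finite circle fits them.

    Carries the span of the offending points so callers can report which
    segment of the bone was (numerically) straight.
    """

    def __init__(self, message: str, span: float | None = None):
        super().__init__(message)
        self.span = span


class AnnotationError(FemurBowError, ValueError):
    """An annotation document is malformed or fails schema validation."""
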