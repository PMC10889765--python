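"""Exception hierarchy for the texture-space transform and classifier."""


class VirtsError(Exception):
    """Base class for all package errors."""


class DimensionError(VirtsError):
    """Image smaller than the 3x3 observation window, or not 2-D."""


class DegeneratePatternError(VirtsError):
    """A 3x3 pattern on which the requested computation is undefined.

    Raised by ``compute_K`` when one of its denominator factors vanishes,
    and by the transform under the ``error`` degenerate policy when the
    2x2 leading minor p11*p22 - p12*p21 vanishes.
    """

    def __init__(self, message, origin=None):
        super().__init__(message)
        self.origin = origin


class UndefinedDirectionError(VirtsError):
    """Direction cosines requested for the zero vector."""


class UndefinedSimilarityError(VirtsError):
    """Cosine similarity requested for a zero-magnitude vector."""


class UnknownLabelError(VirtsError):
    """A label outside the prototype label set."""


class FixtureError(VirtsError):
    """Synthetic fixture generation could not satisfy its contract."""


class VectorParseError(VirtsError):
    """Malformed texture-vector CSV."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
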