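"""Exception hierarchy.

Every error the estimators and simulators can raise derives from
:class:`OifError`, so callers that fill pairwise matrices can catch one
type and degrade gracefully (a failed pair becomes a zero / missing entry).
"""


class OifError(Exception):
    """Base class for all oifnet errors."""


class ZeroVarianceError(OifError):
    """A series is constant where nonzero variance is required."""


class InsufficientDataError(OifError):
    """Too few (overlapping) samples to estimate a quantity robustly."""


class DivergenceError(OifError):
    """A simulated trajectory left the admissible state region."""


class SeriesTooShortError(OifError):
    """A series is too short for the requested embedding or window."""


class NonStationaryError(OifError):
    """An autoregressive coefficient matrix has spectral radius >= 1."""
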