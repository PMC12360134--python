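"""Exception hierarchy for the kinematics pipeline.

Every stage raises a subclass of :class:`UndulokinError`, so callers (and the
pipeline driver) can trap pipeline-specific failures without masking
programming errors.
"""


class UndulokinError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(UndulokinError, ValueError):
    """A domain object violates one of its invariants.

    The message names the offending field.
    """


class ParseError(UndulokinError):
    """A coordinate file row could not be parsed; message cites the row."""


class SchemaError(UndulokinError):
    """A coordinate file has the wrong column layout."""


class NoCompleteCycleError(UndulokinError):
    """Fewer than three same-direction zero crossings in the tip trace."""


class DegenerateInputError(UndulokinError):
    """Geometrically or numerically degenerate input (flat trace,
    coincident landmarks, duplicate midline points)."""


class NoTravelingWaveError(UndulokinError):
    """Phase profile has no usable gradient (standing wave) or the wrong
    propagation direction."""


class InsufficientDataError(UndulokinError):
    """Not enough stations/frames/groups to carry out the computation."""
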