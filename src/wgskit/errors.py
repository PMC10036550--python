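"""Exception hierarchy for wgskit.

All errors derive from :class:`WgsError` so callers can catch package
failures with one handler; most also derive from :class:`ValueError`
because they signal invalid user input rather than internal faults.
"""


class WgsError(Exception):
    """Base class for all wgskit errors."""


class RubricValidationError(WgsError, ValueError):
    """A rating, assessment or rubric definition violates the scale."""


class MissingItemsError(RubricValidationError):
    """An assessment does not rate every rubric item."""

    def __init__(self, missing):
        self.missing = tuple(sorted(missing))
        super().__init__(f"assessment is missing ratings for items: {list(self.missing)}")


class GeometryError(WgsError, ValueError):
    """Degenerate geometry (coincident points, zero-length axis, wrong view)."""


class MissingLandmarkError(GeometryError):
    """A required landmark is absent from a frame."""

    def __init__(self, name, side, frame_index=None):
        self.name, self.side, self.frame_index = name, side, frame_index
        where = f" in frame {frame_index}" if frame_index is not None else ""
        super().__init__(f"missing landmark '{name}' (side '{side}'){where}")


class TimelineError(WgsError, ValueError):
    """Gait-event timeline is inconsistent or lacks a required window."""


class StatsError(WgsError, ValueError):
    """Invalid input to a reliability statistic."""


class IccUndefinedError(StatsError):
    """ICC is undefined (e.g. the score matrix has zero total variance)."""


class SchemaError(WgsError, ValueError):
    """A file does not conform to the annotation/ratings schema."""
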