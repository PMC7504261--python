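"""Exception hierarchy for ergopose.

Every error raised on purpose by this package derives from :class:`ErgoposeError`,
so callers can catch one type at an API boundary.  Per-frame failures inside
series operations are re-raised as :class:`FrameError` carrying the frame index.
"""


class ErgoposeError(Exception):
    """Base class for all ergopose errors."""


class FormatError(ErgoposeError):
    """A kinematics file violates the declared dialect (header, timestamps, units)."""


class ChannelMissingError(FormatError):
    """A mandatory channel is absent from an input file."""

    def __init__(self, channel: str):
        self.channel = channel
        super().__init__(f"mandatory channel missing: {channel!r}")


class SegmentCountError(FormatError):
    """A position file does not carry the full 23-segment layout."""


class MissingFramesError(FormatError):
    """Timestamps reveal a gap in the recording; gaps are never interpolated."""


class ProjectionError(ErgoposeError):
    """Sagittal-plane projection is degenerate (e.g. zero-length pelvis heading)."""


class AngleValidationError(ErgoposeError):
    """A joint angle is outside physiological bounds for its channel."""


class TableLookupError(ErgoposeError):
    """A region score fell outside the domain of a scoring look-up table."""


class EmptyInputError(ErgoposeError):
    """An operation requiring at least one frame/observation received none."""


class FrameError(ErgoposeError):
    """Wraps a per-frame failure with the frame index where it occurred."""

    def __init__(self, frame: int, cause: Exception):
        self.frame = frame
        self.cause = cause
        super().__init__(f"frame {frame}: {cause}")


class ModelIncompleteError(ErgoposeError):
    """A linkage joint required by the biomechanical chain is missing."""


class ConfigurationError(ErgoposeError):
    """A model constant or configuration table is invalid (e.g. negative moment arm)."""


class CoverageError(ErgoposeError):
    """The strength table does not cover a joint/direction that was analysed."""


class UndefinedStatisticError(ErgoposeError):
    """A statistic is undefined on the given data (e.g. zero total variance)."""


class GenerationError(ErgoposeError):
    """A synthetic posture specification is anatomically impossible."""
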