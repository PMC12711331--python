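"""Exception hierarchy.

Every "labeled error" raised by the package derives from :class:`EpiventError`
so callers can distinguish pipeline failures from programming errors.
"""


class EpiventError(Exception):
    """Base class for all epivent errors."""


class SignalIOError(EpiventError):
    """Malformed container, missing channel, or non-uniform sampling."""


class ChannelMissingError(SignalIOError):
    """A required channel label is absent from the container."""


class ScheduleError(EpiventError):
    """A simulation event schedule is inconsistent or exceeds the recording."""


class ParameterError(EpiventError):
    """A parameter is outside its allowed range."""


class InsufficientDataError(EpiventError):
    """Not enough signal or baseline data to apply an operation."""


class SegmentError(EpiventError):
    """No eligible analysis segment exists in the requested window."""
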