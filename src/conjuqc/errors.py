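"""Exception hierarchy for conjuqc."""


class ConjuQCError(Exception):
    """Base class for all conjuqc errors."""


class FormatError(ConjuQCError):
    """A file could not be parsed under the requested dialect."""


class ChannelMappingError(ConjuQCError):
    """A required channel is missing or cannot be mapped."""


class GateError(ConjuQCError):
    """Gating produced an unusable result (e.g. empty gate)."""


class ConfigurationError(ConjuQCError):
    """Invalid user configuration (overlapping bead-code intervals, bad panel, ...)."""


class UndefinedStatisticError(ConjuQCError):
    """A statistic is undefined for the given input (e.g. GM with no positive events)."""


class CalibrationError(ConjuQCError):
    """MESF calibration could not be fitted."""


class SeriesError(ConjuQCError):
    """A time series is unusable (too few timepoints, label mismatch, ...)."""
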