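"""Exception hierarchy shared across the pitchshift modules."""


class PitchShiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PitchShiftError, ValueError):
    """A numeric argument violates a precondition (e.g. non-positive frequency)."""


class EmptySpectrumError(PitchShiftError, ValueError):
    """Band-limiting removed every harmonic; the tone would be silent."""


class UndefinedScoreError(PitchShiftError, ValueError):
    """A Shift Index was requested for a tally with zero responses."""


class UnsupportedDesignError(PitchShiftError, ValueError):
    """An operation defined only for the two-repetition design saw another design."""


class ScheduleError(PitchShiftError, ValueError):
    """The comparison schedule cannot run because conditions are missing."""


class ConfigurationError(PitchShiftError, ValueError):
    """A configuration table (scale, simulation config) is invalid or incomplete."""
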