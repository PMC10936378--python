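"""Exception hierarchy for fogsole.

All validation failures raise a subclass of :class:`FogsoleError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class FogsoleError(Exception):
    """Base class for all fogsole errors."""


class LengthError(FogsoleError):
    """Sequences that must be aligned have different lengths."""


class LayoutError(FogsoleError):
    """A sensor layout is malformed or references unknown sensors."""


class EmptyInputError(FogsoleError):
    """An operation received an empty stream or sequence."""


class AlignmentError(FogsoleError):
    """Left/right streams disagree in length, rate, or origin."""


class InsufficientCalibrationError(FogsoleError):
    """Too few gait episodes to form a calibration baseline."""


class CalibrationRequiredError(FogsoleError):
    """A detection operation was called without a calibration profile."""


class SequencingError(FogsoleError):
    """Samples or timestamps arrived out of order."""


class ParameterError(FogsoleError):
    """A numeric parameter is out of its valid range."""


class DegenerateZoneError(FogsoleError):
    """Threshold training requires both normal and fog labeled instances."""


class InfeasibleTargetError(FogsoleError):
    """A requested distribution statistic cannot be achieved."""


class FormatError(FogsoleError):
    """A file does not conform to the expected dialect."""


class ConfigError(FogsoleError):
    """A configuration object is internally inconsistent."""
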