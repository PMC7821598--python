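"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`MitoclampError`
so callers can catch pipeline failures without swallowing programming errors.
"""


class MitoclampError(Exception):
    """Base class for all mitoclamp contract violations."""


class InvalidInputError(MitoclampError, ValueError):
    """Non-positive concentration, weight, time, or otherwise unusable input."""


class InvalidScheduleError(MitoclampError, ValueError):
    """PCr titration steps are not strictly increasing."""


class NoSolutionError(MitoclampError, ValueError):
    """Requested free-energy target is unreachable with positive PCr."""


class NoSteadyStateError(MitoclampError, RuntimeError):
    """No window in the trace interval satisfies the steady-state policy."""


class ProtocolError(MitoclampError, RuntimeError):
    """Trace lacks an event the assay protocol requires (e.g. the ADP bolus)."""


class InsufficientDataError(MitoclampError, ValueError):
    """Fewer points than the fit requires."""


class SingularDesignError(MitoclampError, ValueError):
    """Zero variance in the predictor; slope is undefined."""


class CurveRejectedError(MitoclampError, ValueError):
    """Standard curve failed its quality gate (non-positive slope or low r^2)."""


class DisallowedConditionError(MitoclampError, ValueError):
    """Condition combination the assay design forbids (succinate leak pairing)."""


class PairingError(MitoclampError, ValueError):
    """JH2O2/JO2 pair does not share substrate and demand condition."""


class NonlinearTraceError(MitoclampError, RuntimeError):
    """No window of the kinetic trace meets the linearity policy."""


class CalibrationError(MitoclampError, ValueError):
    """Calibration mode requires a curve or extinction coefficient not given."""


class DuplicateRowError(MitoclampError, ValueError):
    """Duplicate animal x assay rows in a panel."""


class FitError(MitoclampError, RuntimeError):
    """Nonlinear fit failed to converge."""


class DesignError(MitoclampError, ValueError):
    """Statistical design is unusable (empty cell, single group, ...)."""


class MissingCellError(MitoclampError, ValueError):
    """A sex x group x substrate cell has no samples."""


class AlignmentError(MitoclampError, ValueError):
    """Feature table and phenotype vector do not share samples."""


class UndefinedCorrelationError(MitoclampError, ValueError):
    """Zero variance makes the Pearson correlation undefined."""


class ConfigError(MitoclampError, ValueError):
    """Run configuration failed schema validation."""


class ParseError(MitoclampError, ValueError):
    """Malformed tabular input; message carries the line/column at fault."""
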