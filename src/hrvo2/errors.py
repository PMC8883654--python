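"""Exception hierarchy for the hrvo2 pipeline."""


class HrVo2Error(Exception):
    """Base class for all hrvo2 errors."""


class ValidationError(HrVo2Error):
    """An input value violates a documented invariant."""


class InsufficientDataError(HrVo2Error):
    """A series is too short for the requested window."""


class NoSteadyStateError(HrVo2Error):
    """No steady-state window was found in a submaximal recording."""


class DegenerateFitError(HrVo2Error):
    """A regression cannot be fitted (e.g. zero predictor variance)."""


class ModelCompositionError(HrVo2Error):
    """Calibration points do not match the requested model kind."""


class ContextError(HrVo2Error):
    """A heart-rate-reserve context is invalid (HRmax <= HRrest)."""


class AlignmentError(HrVo2Error):
    """Paired group inputs do not cover the same participants."""


class IncompleteGridError(HrVo2Error):
    """An estimate grid is missing participant x level cells."""


class ConfigError(HrVo2Error):
    """A configuration value is invalid."""


class ParseError(HrVo2Error):
    """A data file could not be parsed; carries row locations."""
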