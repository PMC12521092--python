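"""Named error types for panel validation, LP solving and frontier fitting."""


class DeaequityError(Exception):
    """Base class for all package errors."""


class UnbalancedPanelError(DeaequityError):
    """A (dmu, period, indicator) cell is missing from the panel."""


class InvalidMeasurementError(DeaequityError):
    """A measurement is negative, or an input/output cell is not strictly positive."""


class DuplicateRecordError(DeaequityError):
    """The same (dmu, period, indicator) cell appears more than once."""


class MalformedProblemError(DeaequityError):
    """An envelopment LP is unbounded — only possible on malformed data."""


class InternalLPError(DeaequityError):
    """The LP solver failed on a problem that is feasible by construction."""


class InfeasibleDistanceError(DeaequityError):
    """A cross-period VRS distance LP is infeasible (the classic Malmquist gap)."""


class DegenerateFrontierError(DeaequityError):
    """The slack-regression dependent variable has zero variance."""


class EmptyReferenceRegionError(DeaequityError):
    """Parent totals for a concentration index are zero."""


class ConfigError(DeaequityError):
    """A generator or pipeline configuration is internally inconsistent."""
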