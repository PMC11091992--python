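"""Exception types raised by the analysis pipeline."""


class ImckitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ImckitError, ValueError):
    """Invalid specification, configuration or input arguments."""


class CurveRejectionError(ImckitError):
    """A repetition trace is unusable (too few samples, span too short,
    or no valid samples left after the velocity filter).  Mirrors the
    exclusion of subjects with a limited range of motion."""


class DegenerateCurveError(ImckitError):
    """A curve with no positive torque cannot be peak-normalized."""


class TrialRejectionError(ImckitError):
    """A trial does not contain the repetitions required for analysis."""


class ZeroCellError(ImckitError):
    """A contingency-table cell needed by the saturated multinomial model
    is zero, so the corresponding log-odds diverges.  Callers may opt in
    to an explicit continuity correction instead."""


class FittingError(ImckitError):
    """The iterative model fit failed to converge."""
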