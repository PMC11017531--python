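"""Exception and warning types used across the package."""


class PrevcalError(Exception):
    """Base class for all errors raised by prevcal."""


class UndefinedMetricError(PrevcalError):
    """An operation consumed a statistic whose defining ratio is 0/0.

    Sensitivity is undefined when the test set has no positives, specificity
    when it has no negatives; metrics built on them inherit the gap.  The
    undefined state is carried explicitly (see :data:`prevcal.core.UNDEFINED`)
    and converting it to a number raises this error rather than silently
    producing 0 or 1.
    """


class UndefinedLimitError(PrevcalError):
    """A closed-form metric was requested at a point with no defined limit.

    The MCC prevalence curve is anchored at 0 for prevalence 0 and 1 only when
    sensitivity and specificity are strictly between 0 and 1; at the exempt
    corner cases the limit does not exist and this error is raised instead of
    guessing a value.
    """


class FormatError(PrevcalError):
    """An input file or serialised document is malformed or fails validation."""


class DegenerateLimitWarning(UserWarning):
    """A value was returned by convention at a degenerate (0/0) point.

    Emitted when MCC is reported as its anchor value 0 at prevalence 0 or 1,
    and when the balanced MCC denominator vanishes at |sen - spe| = 1.
    """
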