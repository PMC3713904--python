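"""Exception hierarchy for actipair.

All package-raised errors derive from :class:`ActipairError` so callers can
catch the whole family; subclasses distinguish configuration mistakes from
data problems from statistically undefined requests.
"""


class ActipairError(Exception):
    """Base class for all actipair errors."""


class ConfigurationError(ActipairError):
    """A dialect, manifest or parameter is inconsistent or incomplete."""


class DataError(ActipairError):
    """Input data violate a contract (non-monotone time, negative intensity...)."""


class EmptyInputError(DataError):
    """An operation that requires data received none."""


class UndefinedStatisticError(ActipairError):
    """The requested statistic is undefined for this input (zero variance, n too small)."""


class AlignmentError(ActipairError):
    """The clock-offset scan cannot run; carries per-offset overlap counts."""

    def __init__(self, message, overlap_per_offset=None):
        super().__init__(message)
        self.overlap_per_offset = dict(overlap_per_offset or {})


class FitError(ActipairError):
    """A regression fit is impossible (insufficient points or zero variance)."""


class DomainError(ActipairError):
    """A numeric argument is outside the operation's domain (e.g. negative VT)."""
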