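"""Exception types raised by the revlearn pipeline.

Every stage raises a named subclass of :class:`RevlearnError` so callers can
distinguish contract violations (bad protocol, degenerate reference channel,
truncated analysis window, ...) from ordinary ``ValueError`` noise.
"""


class RevlearnError(Exception):
    """Base class for all revlearn errors."""


class InvalidProtocolError(RevlearnError, ValueError):
    """Trial-schedule protocol is malformed (negative counts, bad phase...)."""


class InvalidConfigError(RevlearnError, ValueError):
    """Simulation configuration violates its invariants."""


class DegenerateReferenceError(RevlearnError, ValueError):
    """Reference (tdTomato) channel is non-positive at some frame."""


class InsufficientBaselineError(RevlearnError, ValueError):
    """Too few unmasked frames to fit the photobleaching trend."""


class NonPositiveBaselineError(RevlearnError, ValueError):
    """Baseline ratio R0 is non-positive; dR/R0 is undefined."""


class TruncatedWindowError(RevlearnError, ValueError):
    """Trace does not cover the requested response window."""


class ContractError(RevlearnError, ValueError):
    """Operation called outside its contract (e.g. shock metric on a no-shock trial)."""


class IncompletePhaseError(RevlearnError, KeyError):
    """A required trial for a (fly, odor, phase) combination is missing."""


class UnbalancedDesignError(RevlearnError, ValueError):
    """Repeated-measures design has unequal per-subject trial coverage."""


class SchemaError(RevlearnError, ValueError):
    """Tabular input is missing a required column."""


class UndefinedIndexError(RevlearnError, ZeroDivisionError):
    """Preference index is undefined (zero classified flies)."""
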