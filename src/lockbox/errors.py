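"""Exception hierarchy for the lockbox analysis pipeline.

All package-specific failures derive from :class:`LockboxError`, so callers
(including the CLI) can distinguish data problems from programming errors.
"""


class LockboxError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LockboxError):
    """A file does not conform to the expected CSV dialect (e.g. a missing
    column or an unparsable cell)."""


class ValidationError(LockboxError):
    """Structurally well-formed input violates a domain invariant
    (non-increasing timestamps, unknown component label, broken state
    continuity between sessions, ...)."""


class MechanicalImpossibilityError(ValidationError):
    """An event claims to open a lock that cannot open in the current task
    state (e.g. the bar opening while the wheel is still attached)."""


class IncompleteEpisodeError(LockboxError):
    """A per-episode metric was requested for an episode whose final lock was
    never opened; mistargeting is undefined there."""


class InsufficientDataError(LockboxError):
    """Too few data points for the requested fit."""


class StallError(LockboxError):
    """Simulation parameters imply (or produced) an episode longer than the
    configured hard cap on simulated contacts."""
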