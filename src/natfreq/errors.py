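"""Exception hierarchy shared across the package."""


class NatfreqError(Exception):
    """Base class for all domain errors raised by natfreq."""


class MalformedInputError(NatfreqError):
    """Input text could not be parsed into the documented schema."""


class TaskValidationError(NatfreqError):
    """A task or tree violates its invariants.

    Carries the full list of violations so callers can report them all.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class DomainError(NatfreqError):
    """An operation was called with values outside its domain
    (unknown hypothesis, unknown category, missing cue value, ...)."""


class UndefinedPosteriorError(NatfreqError):
    """Conditioning on an event of probability (or frequency) zero."""


class UndefinedValidityError(NatfreqError):
    """A cue validity has no defined value (no discriminating pairs)."""
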