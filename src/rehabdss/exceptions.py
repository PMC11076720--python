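"""Exception hierarchy for the decision-support system.

Every error the library raises deliberately derives from
:class:`RehabDSSError`, so callers can catch one base class at the
application boundary while tests assert on the specific subclass.
"""


class RehabDSSError(Exception):
    """Base class for all errors raised by rehabdss."""


class InvalidMeasurementError(RehabDSSError):
    """Work measurements cannot yield a defined engagement (e.g. W_total <= W_robot)."""


class UndefinedFitnessError(RehabDSSError):
    """Trajectory fitness is undefined (constant actual trajectory, n < 2, ...)."""


class MalformedSessionError(RehabDSSError):
    """Session signal streams are empty, length-mismatched or out of range."""


class UnsupportedAssessmentError(RehabDSSError):
    """Patient assessment falls outside the rule base (Brunnstrom stage or tone)."""


class DuplicateCaseError(RehabDSSError):
    """A case with the same id already exists in the library."""


class NoCasesError(RehabDSSError):
    """The per-mode case partition queried for retrieval is empty."""


class UnlearnableError(RehabDSSError):
    """The training library contains a single label class."""


class WrongModelError(RehabDSSError):
    """A model fitted for one training mode was asked to score another mode's session."""


class SchemaMismatchError(RehabDSSError):
    """Feature names presented to a persisted model do not match its training schema."""


class DegenerateColumnError(RehabDSSError):
    """A column with zero spread where positive spread is required (standardization)."""
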