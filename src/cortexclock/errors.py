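"""Exception types shared across the package."""


class CortexClockError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CortexClockError, ValueError):
    """An argument violates a documented precondition (e.g. non-positive age)."""


class InsufficientDataError(CortexClockError, ValueError):
    """Too few observations for the requested fit."""


class UnrepresentableWindowError(CortexClockError, ValueError):
    """A developmental window cannot be expressed as FA-decay fractions.

    Raised when a window starts before ``t_init``: on the pre-decay plateau the
    decay fraction saturates at 1, so the mapping age -> fraction is not
    invertible there.
    """


class SpeciesMismatchError(CortexClockError, ValueError):
    """Two objects that must refer to the same species do not."""
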