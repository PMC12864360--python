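"""Structured exceptions shared across the package."""

from __future__ import annotations

__all__ = [
    "EffortChoiceError",
    "IncompleteProfileError",
    "ValidationError",
    "DegenerateInputError",
    "WrongPhaseError",
]


class EffortChoiceError(Exception):
    """Base class for package errors."""


class IncompleteProfileError(EffortChoiceError):
    """A performance profile is missing one or more of the six options."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        names = ", ".join(str(o) for o in self.missing)
        super().__init__(f"incomplete profile: missing option(s) {names}")


class ValidationError(EffortChoiceError):
    """Malformed input data (bad counts, duplicate rows, unknown ids)."""

    def __init__(self, message, row=None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DegenerateInputError(EffortChoiceError):
    """A statistic is undefined for the given input (e.g. zero spread)."""


class WrongPhaseError(EffortChoiceError):
    """A titration operation was applied to a trace from the other phase."""
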