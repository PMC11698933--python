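"""Exception and warning hierarchy.

Errors map onto CLI exit codes: :class:`UsageError` and :class:`DomainError`
are input/usage problems (exit 2); anything else is internal (exit 1).
"""


class FluoriskError(Exception):
    """Base class for package errors."""


class DomainError(FluoriskError, ValueError):
    """An input value violates a physical or mathematical precondition."""


class ConfigurationError(FluoriskError, ValueError):
    """A configuration object is internally inconsistent."""


class UsageError(FluoriskError, ValueError):
    """A call violates an operation contract (empty input, bad combination)."""


class GenerationError(FluoriskError, ValueError):
    """Synthetic-data targets are infeasible."""


class ValidationWarning(UserWarning):
    """Non-fatal inconsistency in supplied parameters."""


class ExtrapolationWarning(UserWarning):
    """Surrogate queried outside (or near the edge of) its training hull."""


class TrainingWarning(UserWarning):
    """Surrogate training ended without meeting its stopping rule."""
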