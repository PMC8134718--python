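"""Exception hierarchy for cohort ingest and model configuration."""


class OncoDelayError(Exception):
    """Base class for all package errors."""


class ParseError(OncoDelayError):
    """A CSV row could not be parsed; the message names the offending line."""


class IntegrityError(OncoDelayError):
    """Duplicate record keys or inconsistent aggregate rows."""


class ValidationError(OncoDelayError):
    """A value violates a domain invariant (negative count, bad stratum...)."""


class DegenerateTableError(ValidationError):
    """A 2x2 contingency table has an empty margin."""


class UndefinedFractionError(ValidationError):
    """A reduction fraction is undefined because the reference count is zero."""


class UndefinedRatioError(ValidationError):
    """A month ratio is undefined because the denominator is zero."""


class ParameterError(ValidationError):
    """Risk parameters outside their domain (RD not in (0,1), HR <= 0)."""


class ScheduleError(ValidationError):
    """Resolution month precedes the end of the shortfall window."""


class ScenarioError(ValidationError):
    """A scenario shift makes a monthly reduction fraction reach 100%."""


class ConfigError(ValidationError):
    """Invalid generator or CLI configuration."""
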