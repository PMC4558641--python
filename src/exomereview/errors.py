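"""Exception hierarchy for the triage engine."""

from __future__ import annotations


class ExomeReviewError(Exception):
    """Base class for all package errors."""


class FormatError(ExomeReviewError):
    """A table file violates the expected format (e.g. missing column)."""


class RowError(FormatError):
    """A single data row is invalid; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class HgvsParseError(ExomeReviewError):
    """A nucleotide/protein alteration string could not be interpreted.

    Carries the raw string: upstream nomenclature can simply be wrong and the
    reviewer needs to see it verbatim.
    """

    def __init__(self, raw: str, reason: str = "unrecognised nomenclature"):
        super().__init__(f"{reason}: {raw!r}")
        self.raw = raw


class RuleNotApplicableError(ExomeReviewError):
    """A classification rule was invoked outside its domain."""


class NotEvaluableError(ExomeReviewError):
    """A rule cannot be evaluated because required fields are missing."""


class StoreError(ExomeReviewError):
    """The annotation store file is invalid (unknown source, duplicates)."""


class ConfigurationError(ExomeReviewError):
    """Project configuration is inconsistent with the requested operation."""


class AuthorizationError(ExomeReviewError):
    """A reviewer acted on a variant that was never assigned to them."""


class CallValidationError(ExomeReviewError):
    """A call uses a label outside its allowed context (footnote conditions)."""


class WorkflowError(ExomeReviewError):
    """An operation was attempted out of lifecycle order."""


class StalenessError(WorkflowError):
    """Director sign-off attempted on report tables older than the project."""


class MatrixValidationError(ExomeReviewError):
    """The shipped decision matrix failed its totality/consistency audit.

    ``problems`` lists every offending cell or check.
    """

    def __init__(self, problems: list[str]):
        super().__init__(
            "decision matrix validation failed:\n  " + "\n  ".join(problems)
        )
        self.problems = problems


class FixtureSpecError(ExomeReviewError):
    """A synthetic-case specification is contradictory or out of range."""
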