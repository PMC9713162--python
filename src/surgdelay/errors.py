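"""Exception hierarchy shared across the package."""


class SurgDelayError(Exception):
    """Base class for all package errors."""


class DomainError(SurgDelayError, ValueError):
    """An input violates a documented precondition or type invariant."""


class SchemaError(SurgDelayError, ValueError):
    """A tabular input file violates its declared schema.

    Carries a list of row-level messages in ``problems``.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = problems or []
        detail = "".join(f"\n  - {p}" for p in self.problems)
        super().__init__(message + detail)


class ConsistencyError(SurgDelayError, ValueError):
    """Two objects that must describe the same computation disagree."""


class ConvergenceError(SurgDelayError, RuntimeError):
    """An iterative fit failed to converge."""
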