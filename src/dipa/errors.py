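"""Exception hierarchy shared across the package."""


class DipaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DipaError, ValueError):
    """An input value violates a documented precondition."""


class TableError(DipaError, ValueError):
    """The conversion-factor table is malformed or inconsistent."""


class DrugLookupError(DipaError, KeyError):
    """A prescription names an opioid absent from the conversion table."""

    def __init__(self, names):
        self.names = sorted(set(names))
        super().__init__(
            "opioid drug name(s) not found in conversion table: "
            + ", ".join(repr(n) for n in self.names)
        )


class InconsistentVisitError(DipaError, ValueError):
    """Visit-level flags contradict the computed daily MME."""


class DegenerateDataError(DipaError, ValueError):
    """Too few distinct values for the requested clustering."""


class InsufficientDataError(DipaError, ValueError):
    """Sample too small (or too degenerate) for a statistical test."""


class SchemaError(DipaError, ValueError):
    """A cohort or report file does not match the documented schema."""
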