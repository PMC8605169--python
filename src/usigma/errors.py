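"""Exception hierarchy.

All package errors derive from :class:`UsigmaError` so callers can catch one
base class at pipeline boundaries.
"""


class UsigmaError(Exception):
    """Base class for all usigma errors."""


class SchemaError(UsigmaError):
    """An input file is missing a required column or has the wrong layout."""


class ValidationError(UsigmaError):
    """A value violates a domain invariant (e.g. non-positive concentration).

    ``row`` carries the 1-based file row (header = row 1) when the violation
    was found while reading a file, else None.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (file row {row})"
        super().__init__(message)
        self.row = row


class InsufficientDataError(UsigmaError):
    """Too few observations for the requested statistic."""


class ComputationError(UsigmaError):
    """A metric's preconditions are not met (e.g. CV from a non-positive mean)."""


class UnknownAnalyteError(UsigmaError, KeyError):
    """An analyte code has no entry in the active quality-goal table."""

    def __init__(self, analyte_id: str):
        super().__init__(f"no TEa quality goal defined for analyte {analyte_id!r}")
        self.analyte_id = analyte_id


class UnknownRuleError(UsigmaError):
    """A control-rule code is not in the implemented Westgard grammar."""

    def __init__(self, code: str):
        super().__init__(f"unknown control rule code {code!r}")
        self.code = code
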