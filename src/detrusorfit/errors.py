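"""Exception types shared across the package."""


class DetrusorFitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DetrusorFitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(DetrusorFitError, ValueError):
    """Too few observations to identify the requested model."""


class InvalidInputError(DetrusorFitError, ValueError):
    """Non-finite or otherwise malformed input values."""


class UndefinedResultError(DetrusorFitError, ValueError):
    """The requested quantity is undefined for these inputs (e.g. zero amplitude)."""


class IncompatibleFitsError(DetrusorFitError, ValueError):
    """Two fits cannot be compared (different data or non-nested models)."""


class CalibrationError(DetrusorFitError, ValueError):
    """A calibration line cannot be determined from the standards given."""


class PairingError(DetrusorFitError, ValueError):
    """Paired data are unequal in length or cannot be matched by preparation."""


class DegenerateTestError(DetrusorFitError, ValueError):
    """A statistical test is undefined (zero variance, empty cells)."""


class IncompleteDesignError(DetrusorFitError, ValueError):
    """A repeated-measures table has missing preparation x condition cells."""


class DesignError(DetrusorFitError, ValueError):
    """A simulated study design is invalid (e.g. cohort size below 2)."""


class MissingColumnError(DetrusorFitError, KeyError):
    """An input table lacks a required named column."""

    def __init__(self, column: str, table: str = "input"):
        self.column = column
        self.table = table
        super().__init__(f"{table} table is missing required column {column!r}")
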