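"""Exception hierarchy for pipeline error contracts."""


class DmsImpactError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDatasetError(DmsImpactError):
    """A DMS dataset is empty or too small after filtering to normalize."""


class ConsistencyError(DmsImpactError):
    """Conflicting wild-type residues, coordinates or sequence lengths."""


class SingularDesignError(DmsImpactError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class MissingCellError(DmsImpactError):
    """A substitution-matrix cell needed for a computation is unobserved."""


class BlastParseError(DmsImpactError):
    """A blastp tabular line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class BlastEnvironmentError(DmsImpactError):
    """The external blastp executable or database is unavailable."""
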