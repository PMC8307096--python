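"""Exception types shared across the package."""


class CohortValidationError(ValueError):
    """A cohort record or file violates the schema.

    Carries enough context (row, column) to locate the offending cell.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column '{column}'")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)
        self.row = row
        self.column = column


class InsufficientSamplesError(ValueError):
    """Too few posterior draws to summarize."""


class DegenerateInputError(ValueError):
    """Input carries no usable information (constant vector, empty group, ...)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
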