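"""Exception types shared across the package."""


class PalynError(ValueError):
    """Base class for domain validation and computation errors."""


class TableValidationError(PalynError):
    """A tabular input violated an invariant.

    Carries the offending row/column identity so the user can fix the file;
    nothing is coerced silently.
    """

    def __init__(self, message: str, *, row=None, column=None):
        ctx = []
        if row is not None:
            ctx.append(f"row={row!r}")
        if column is not None:
            ctx.append(f"column={column!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.row = row
        self.column = column


class AgeModelError(PalynError):
    """Tie points are unusable or a depth falls outside the modelled span."""
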