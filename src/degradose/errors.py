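"""Exception hierarchy.

Domain/configuration problems raise :class:`ConfigurationError`; malformed
input files raise :class:`InputError` carrying file/record/field context.
Field-level type and bound violations are left to pydantic.
"""


class DegradoseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DegradoseError):
    """A domain object is internally inconsistent or incomplete
    (e.g. molar-basis polymer missing a repeat-unit mass, orphan CAS)."""


class InputError(DegradoseError):
    """An input document failed validation.

    Parameters
    ----------
    message:
        Human-readable description.
    path, record, field:
        Where the problem was found, when known.
    """

    def __init__(self, message: str, *, path: str | None = None,
                 record: str | int | None = None, field: str | None = None):
        self.path = path
        self.record = record
        self.field = field
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if record is not None:
            ctx.append(f"record={record}")
        if field is not None:
            ctx.append(f"field={field}")
        super().__init__(message + (f" [{', '.join(ctx)}]" if ctx else ""))


class CurveWindowError(DegradoseError):
    """The requested sliding window is longer than the observed time range.

    Extend the mass-loss data or fall back to total observed loss."""
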