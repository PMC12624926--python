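"""Exception hierarchy for the pipeline."""


class OperantDBError(Exception):
    """Base class for all package errors."""


class MedPCParseError(OperantDBError):
    """Raised when a MedPC raw session file violates the dialect grammar."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)


class FilenameError(OperantDBError):
    """Raised when a session filename does not match the naming grammar.

    ``element`` names the grammar element that failed (location, computer,
    cohort, drug, session_type, session_index, structure) so that naming
    mistakes surface as actionable gap diagnostics rather than silent drops.
    """

    def __init__(self, name: str, element: str, message: str):
        self.name = name
        self.element = element
        super().__init__(f"{name!r}: bad {element}: {message}")


class SchemaError(OperantDBError):
    """Raised when a workbook or metadata template is missing mandatory
    structure (row, column or sheet), naming the offending element."""


class TemplateError(OperantDBError):
    """Raised on invalid cell content in a metadata template (unknown enum
    value, duplicated RFID, unparseable date), naming row and column."""


class StoreError(OperantDBError):
    """Raised on relational-store contract violations."""


class ReleaseExistsError(OperantDBError):
    """Raised when a stable release would overwrite an existing one."""
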