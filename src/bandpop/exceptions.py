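"""Exception hierarchy for bandpop."""


class BandpopError(Exception):
    """Base class for all bandpop errors."""


class ValidationError(BandpopError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(BandpopError, ValueError):
    """A band-matrix file could not be parsed.

    Carries the 1-based ``row`` and ``column`` of the offending cell when
    known, so error messages can point at the file location.
    """

    def __init__(self, message: str, *, row: int | None = None,
                 column: int | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column
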