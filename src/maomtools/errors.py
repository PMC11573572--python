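"""Exception types shared across the package."""


class MaomError(Exception):
    """Base class for all package errors."""


class ParseError(MaomError):
    """A coordinate or topology file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number at which parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(MaomError):
    """Unsupported or inconsistent file format."""


class GeometryError(MaomError):
    """Invalid box, cutoff, or coordinate geometry."""


class PlacementError(MaomError):
    """A synthetic-scene placement could not be satisfied."""


class SurfaceError(MaomError):
    """The liquid surface or atomic layers could not be located."""


class SchemaError(MaomError):
    """Mismatched or incomplete tabular/ensemble schemas."""
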