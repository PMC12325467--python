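"""Exception hierarchy for shellont.

All errors raised by the package derive from :class:`ShellOntError` so callers
can catch the package's failures without masking programming errors.
"""


class ShellOntError(Exception):
    """Base class for all shellont errors."""


class DimensionError(ShellOntError):
    """Landmark count or coordinate dimensionality mismatch."""


class FormatError(ShellOntError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class IntegrityError(ShellOntError):
    """Duplicate identifiers or inconsistent metadata."""


class SpeciesLookupError(ShellOntError):
    """A species is missing from a lookup table (e.g. maximum-size records)."""


class SampleSizeError(ShellOntError):
    """Too few specimens for the requested operation."""


class DegenerateDataError(ShellOntError):
    """Input with no usable variation (coincident landmarks, constant predictor,
    flat trajectory)."""


class ConvergenceError(ShellOntError):
    """An iterative procedure failed to converge within its budget."""
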