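"""Exception types shared across the package."""


class LfmoveError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(LfmoveError):
    """A geometric input is malformed (non-finite coordinates, invalid rings, zero area)."""


class DegenerateInputError(LfmoveError):
    """Input is structurally valid but degenerate for the requested operation."""


class UnsupportedOperationError(LfmoveError):
    """The requested operation is outside the supported domain (e.g. negative buffer)."""


class UnresolvedFixError(LfmoveError):
    """No pair of GPS readings for a relocation agree within the 3 m protocol."""


class DegenerateFitError(LfmoveError):
    """A model fit cannot proceed (e.g. zero-variance data)."""


class NonIdentifiableError(LfmoveError):
    """A model covariate carries no usable contrast."""


class ValidationError(LfmoveError):
    """A configuration or input table violates its schema."""
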