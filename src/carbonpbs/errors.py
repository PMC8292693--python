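"""Exception types shared across the package."""


class CarbonPbsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CarbonPbsError, ValueError):
    """A physical parameter is outside its valid domain (e.g. non-positive)."""


class DegenerateInputError(CarbonPbsError, ValueError):
    """Input data is structurally valid but degenerate for the requested operation."""


class FitFailureError(CarbonPbsError, RuntimeError):
    """A fitting procedure failed to converge or produced a non-physical solution."""


class SchemaError(CarbonPbsError, ValueError):
    """A file does not conform to the documented format."""
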