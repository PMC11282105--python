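"""Exception types shared across the package."""


class TexdiscError(Exception):
    """Base class for all package errors."""


class ParameterError(TexdiscError, ValueError):
    """An analysis or simulation parameter is outside its valid domain."""


class DesignError(TexdiscError, ValueError):
    """A session design is internally inconsistent or unsatisfiable."""


class AlignmentError(TexdiscError, ValueError):
    """A trial window does not fit inside the recording."""


class FormatError(TexdiscError, ValueError):
    """An input file violates the documented schema."""


class FitError(TexdiscError, ValueError):
    """A model fit cannot be attempted on the given data."""
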