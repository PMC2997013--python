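"""Exception hierarchy used across the package."""


class MiteKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MiteKitError, ValueError):
    """A file could not be parsed (message names the offending line)."""


class ValidationError(MiteKitError, ValueError):
    """Structurally invalid input (e.g. exon outside its parent gene)."""


class ParameterError(MiteKitError, ValueError):
    """An argument is outside its admissible range."""


class PackingError(MiteKitError, RuntimeError):
    """Planted features cannot be packed into the requested genome length."""


class UndefinedInputError(MiteKitError, ValueError):
    """The requested quantity is undefined for this input (e.g. all-N sequence)."""


class SaturationError(MiteKitError, ArithmeticError):
    """Distance correction is undefined because substitutions are saturated."""
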