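"""Exception types raised across the package."""


class AcetrnaError(Exception):
    """Base class for package errors."""


class InputError(AcetrnaError, ValueError):
    """Malformed or out-of-range user input (files, tables, parameters)."""


class StructureError(AcetrnaError, ValueError):
    """A secondary-structure string is not a valid tRNA cloverleaf."""


class DesignError(AcetrnaError, ValueError):
    """A requested cassette or oligo design is internally inconsistent."""


class FitError(AcetrnaError, RuntimeError):
    """Model fitting failed to converge or the data are degenerate."""
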