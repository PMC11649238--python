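"""Exception hierarchy.

``ParameterError`` covers user-facing argument problems (CLI exit code 1);
anything else escaping the library is treated as internal (exit code 2).
"""


class RPMaxEntError(Exception):
    """Base class for all package errors."""


class ParameterError(RPMaxEntError, ValueError):
    """An argument value violates a documented precondition."""


class ShapeError(RPMaxEntError, ValueError):
    """Array dimensions are inconsistent with each other."""


class EnumerationCapError(ParameterError):
    """Population too large for exact 2^n enumeration; use sampling/AIS."""


class DegenerateProjectionError(RPMaxEntError, ValueError):
    """A normalization target (row/column/total weight norm) is zero."""


class UnsupportedConfigurationError(RPMaxEntError, ValueError):
    """A valid-looking configuration that the method cannot support
    (e.g. reshaping a Heaviside model, whose weight gradient vanishes a.e.)."""


class SchemaError(RPMaxEntError, ValueError):
    """A model or raster file does not match the expected on-disk schema."""


class ParseError(RPMaxEntError, ValueError):
    """A delimited-text raster contains non-binary or malformed entries."""


class ConvergenceError(RPMaxEntError, RuntimeError):
    """An iterative procedure failed to reach its target (e.g. the synthetic
    generator could not land the firing rates in the requested range)."""
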