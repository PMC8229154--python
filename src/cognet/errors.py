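"""Exception hierarchy shared across the pipeline stages."""


class CognetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CognetError):
    """Input data violates a documented contract (bad key, bad label, missing column)."""


class ShapeError(CognetError):
    """Array dimensions or grids are inconsistent."""


class RankError(CognetError):
    """A matrix does not have the rank an operation requires."""


class SizingError(CognetError):
    """A simulation grid is too small to host the requested sources."""


class ParameterError(CognetError):
    """A numeric parameter is outside its admissible range."""


class DegenerateError(CognetError):
    """A degenerate input (constant map, zero variance) makes the result undefined."""
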