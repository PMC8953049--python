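"""Exception hierarchy shared by all pipeline stages."""


class VascupetError(Exception):
    """Base class for all package errors."""


class ValidationError(VascupetError, ValueError):
    """Input fails a value-level contract (empty mask, negative dose, ...)."""


class GeometryError(VascupetError):
    """Two grids that must be congruent (shape + spacing) are not."""


class UnitError(VascupetError):
    """Operation applied to a volume with the wrong unit tag."""


class DegenerateInputError(VascupetError):
    """Input admits no meaningful answer (e.g. all paired differences zero,
    or fewer than three distinct values for a three-class threshold)."""
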