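"""Exception hierarchy shared across the package."""


class ForestQGError(Exception):
    """Base class for all package errors."""


class ParameterError(ForestQGError, ValueError):
    """An argument is outside its documented range."""


class StructuralError(ForestQGError, ValueError):
    """Inputs are structurally inconsistent (cycles, id mismatches, ranks)."""


class DataError(ForestQGError, ValueError):
    """A data value violates a precondition (negative width, nonpositive log)."""


class NumericalError(ForestQGError, ArithmeticError):
    """A numerical operation failed (singular system, non-monotone EM)."""
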