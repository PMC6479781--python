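"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`InputError` and subclasses -> 2,
:class:`NumericalError` and subclasses -> 3.
"""


class GaitcalError(Exception):
    """Base class for all package-specific errors."""


class InputError(GaitcalError, ValueError):
    """Invalid or malformed input data (files, series, arguments)."""


class ConfigurationError(InputError):
    """Invalid configuration values."""


class MissingLandmarkError(InputError):
    """A required marker / landmark is absent from a series."""

    def __init__(self, name: str, dialect: str = ""):
        self.name = name
        where = f" in {dialect} series" if dialect else ""
        super().__init__(f"required landmark {name!r} is missing{where}")


class DegenerateGeometryError(InputError):
    """Points are collinear/coincident so a segment frame cannot be built."""


class NumericalError(GaitcalError, ArithmeticError):
    """A computation failed numerically (singular fit, non-finite values)."""


class DivergenceError(NumericalError):
    """Training diverged (non-finite loss). Lower the learning rate."""
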