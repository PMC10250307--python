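"""Exception hierarchy.

Every contract violation raises a subclass of :class:`OctaAsymError` so
pipeline code can distinguish "bad input" from genuine bugs.
"""


class OctaAsymError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(OctaAsymError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class ValidationError(OctaAsymError, ValueError):
    """An input object violates one of its documented invariants."""


class DegenerateImageError(OctaAsymError):
    """The image histogram does not support the requested operation."""


class NoFazError(OctaAsymError):
    """No avascular region contains the image centre."""


class UnboundedFazError(OctaAsymError):
    """The central avascular region touches the image border."""


class TooSmallRegionError(OctaAsymError):
    """A segmented region is too small for shape metrics."""


class EmptyRoiError(OctaAsymError, ZeroDivisionError):
    """A density was requested over an empty region of interest."""


class UndefinedAsymmetryError(OctaAsymError):
    """Asymmetry index is undefined because both eyes measure zero."""


class InsufficientDataError(OctaAsymError):
    """Too few observations for the requested statistical procedure."""


class DegenerateDataError(OctaAsymError):
    """The data are constant or single-level where variation is required."""


class CollinearityError(OctaAsymError):
    """The regression design matrix is rank deficient."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "rank-deficient design; aliased columns: " + ", ".join(self.aliased)
        )


class SchemaError(OctaAsymError):
    """A table does not match the documented column schema."""
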