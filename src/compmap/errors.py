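"""Exception types raised across the package.

All inherit from :class:`CompmapError` so callers can catch package errors
with one clause; most also inherit from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class CompmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CompmapError, ValueError):
    """A cohort/simulation specification violates its invariants."""


class CoordinateError(CompmapError, ValueError):
    """A mm coordinate falls outside the image field of view."""


class UnsupportedGeometryError(CompmapError, ValueError):
    """The affine contains shear/oblique axes the operation cannot handle."""


class GeometryError(CompmapError, ValueError):
    """Images that must share a grid/affine do not."""


class EmptyRegionError(CompmapError, ValueError):
    """A sphere or cluster selects no voxels."""


class DesignError(CompmapError, ValueError):
    """A GLM design matrix is malformed or rank deficient."""


class CollinearityError(DesignError):
    """Regression design is numerically collinear; names offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class DegenerateNuisanceError(CompmapError, ValueError):
    """A nuisance regressor is (near-)identical to the seed series."""


class InvalidCountsError(CompmapError, ValueError):
    """n-back counts violate their invariants (e.g. zero denominators)."""


class DegeneracyError(CompmapError, ValueError):
    """A data matrix is degenerate for the requested decomposition."""


class MissingDataError(CompmapError, ValueError):
    """Missing values where the operation requires complete data."""
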