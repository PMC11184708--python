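"""Exception hierarchy shared across the package."""


class FcdmapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FcdmapError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(FcdmapError):
    """An image has the wrong number of dimensions."""


class GeometryError(FcdmapError):
    """Two objects do not share a voxel grid, or a location falls outside it."""


class ValidationError(FcdmapError):
    """Tabular input violates the cohort schema."""


class ParameterError(FcdmapError):
    """A numerical parameter is outside its valid range."""


class DesignError(FcdmapError):
    """A statistical design matrix is rank-deficient or malformed."""
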