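"""Exception types shared across the package."""


class ReefstructError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(ReefstructError, ValueError):
    """File format or raster geometry the package does not handle."""


class MalformedInputError(ReefstructError, ValueError):
    """A file that parses but violates the format's own contract."""


class EmptyInputError(ReefstructError, ValueError):
    """An operation received no valid cells / rows to work on."""


class DegenerateSurfaceError(ReefstructError, ValueError):
    """Too few valid cells to triangulate a surface."""


class AlignmentError(ReefstructError, ValueError):
    """DEM and benthic mask do not share grid geometry."""


class SingularDesignError(ReefstructError, ValueError):
    """Regression design is rank deficient on every candidate subset."""
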