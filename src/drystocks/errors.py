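"""Exception hierarchy for drystocks."""


class DrystocksError(Exception):
    """Base class for all package errors."""


class GeometryError(DrystocksError):
    """Invalid grid geometry (non-positive cell size, extent off the sphere, ...)."""


class AlignmentError(DrystocksError):
    """Rasters that must share a grid do not."""


class GeoreferencingError(DrystocksError):
    """A raster file lacks the geometry metadata needed to place it on the globe."""


class UnitError(DrystocksError):
    """A raster's units tag does not match what the operation requires."""


class DepthError(DrystocksError):
    """A depth target lies below the deepest described soil layer."""


class ValidationError(DrystocksError):
    """Input values violate a physical domain constraint (negative stds, AI < 0, ...)."""


class CompositionError(DrystocksError):
    """Map-unit component fractions do not form a valid partition."""


class PipelineStageError(DrystocksError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
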