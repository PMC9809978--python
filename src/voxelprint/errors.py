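"""Exception hierarchy shared across the pipeline.

Each stage raises a subclass of :class:`VoxelPrintError`; the CLI maps the
broad categories onto process exit codes (config/parameter errors, data or
geometry errors, I/O errors).
"""


class VoxelPrintError(Exception):
    """Base class for all voxelprint errors."""


class ParameterError(VoxelPrintError, ValueError):
    """An argument or configuration value violates its contract."""


class ReadError(VoxelPrintError):
    """An input file is missing, unreadable, or corrupt."""


class GeometryError(VoxelPrintError):
    """Volume geometry is inconsistent (shapes, spacings, extents)."""


class DomainError(VoxelPrintError, ValueError):
    """A value lies outside the domain a stage was built for."""


class EmptyRegionError(DomainError):
    """A region contains no material pixels."""


class EmptyMeshError(DomainError):
    """A division contains no voxels, so no surface can be extracted."""


class NonWatertightError(VoxelPrintError):
    """A mesh remained open after the repair pass.

    Carries ``boundary_edges``, the number of edges referenced by a single
    face (a proxy for hole size).
    """

    def __init__(self, message: str, boundary_edges: int = 0):
        super().__init__(message)
        self.boundary_edges = boundary_edges


class OutputError(VoxelPrintError, IOError):
    """Writing an artifact failed."""


class GeometryWarning(UserWarning):
    """Non-fatal geometric oddity (e.g. a phantom shape clipped by the grid)."""
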