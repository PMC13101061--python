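"""Exception hierarchy.

Every error raised by this package derives from :class:`DiffuscopeError` so
callers (and the CLI, which maps exception classes to exit codes) can
distinguish bad arguments, malformed data, and numerical degeneracies.
"""


class DiffuscopeError(Exception):
    """Base class for all package errors."""


class DomainError(DiffuscopeError, ValueError):
    """An argument is outside the physical/mathematical domain of an operation."""


class DegenerateGeometryError(DomainError):
    """A paraxial construction is degenerate (vanishing denominator, pole)."""


class SamplingError(DomainError):
    """A simulation grid is too coarse for the requested field (aliasing)."""


class IllPosedError(DiffuscopeError):
    """An unregularized inversion was requested for a transfer function with
    (near-)zeros."""


class GeometryError(DiffuscopeError, ValueError):
    """Incompatible image geometries (shape or pixel-pitch mismatch)."""


class DataError(DiffuscopeError):
    """Input raster data is invalid (non-finite values, wrong structure)."""


class FormatError(DiffuscopeError):
    """Unsupported file format or dtype."""


class PipelineError(DiffuscopeError):
    """A pipeline stage failed; carries the stage name and input digests."""

    def __init__(self, stage: str, message: str, input_hashes: dict | None = None):
        self.stage = stage
        self.input_hashes = input_hashes or {}
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
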