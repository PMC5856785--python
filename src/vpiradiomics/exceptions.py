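"""Exception types shared across the pipeline."""


class VpiRadiomicsError(Exception):
    """Base class for all package errors."""


class ParameterError(VpiRadiomicsError, ValueError):
    """An input parameter is outside its valid range."""


class DegenerateMaskError(VpiRadiomicsError, ValueError):
    """A segmentation mask is empty or became empty after a morphological operation."""


class EmptyMatrixError(VpiRadiomicsError, ValueError):
    """A co-occurrence or run-length matrix has no counts (no valid voxel pairs/runs)."""


class StageError(VpiRadiomicsError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
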