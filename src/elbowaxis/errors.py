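"""Exception types shared across the pipeline."""


class ElbowAxisError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(ElbowAxisError):
    """Input geometry is degenerate (coincident, collinear, parallel...)."""


class DegenerateProjectionError(DegenerateInputError):
    """A direction is (near-)parallel to the plane normal it is projected on."""


class EmptyIntersectionError(ElbowAxisError):
    """A slicing plane or probing line does not intersect the mesh."""


class LandmarkError(ElbowAxisError):
    """Landmark file is malformed or fails validation."""


class GenerationError(ElbowAxisError):
    """A synthetic specimen request is geometrically unrealizable."""


class StageError(ElbowAxisError):
    """Wraps a failure in one stage of the per-specimen pipeline."""

    def __init__(self, stage: str, specimen_id: str, cause: Exception):
        self.stage = stage
        self.specimen_id = specimen_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for specimen '{specimen_id}': {cause}")
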