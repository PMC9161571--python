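"""Exception hierarchy for the evrad pipeline."""


class EvradError(Exception):
    """Base class for all evrad errors."""


class ValidationError(EvradError, ValueError):
    """Invalid input or configuration."""


class UndefinedRatioError(ValidationError):
    """A blot band is non-positive, so the CD9-normalized ratio is undefined."""


class PlacementError(EvradError):
    """A lesion or muscle VOI cannot be placed inside the image grid."""


class ConsistencyError(EvradError):
    """Patient ids or files disagree between cohort tables."""


class ZeroVarianceError(ValidationError):
    """The muscle VOI has constant intensity; z-normalization is undefined."""


class EmptyGLCMError(EvradError):
    """No in-mask voxel pair exists for the requested offset."""


class AggregationError(EvradError):
    """Fewer than two directions contributed to rotation-invariant aggregation."""


class ConvergenceError(EvradError):
    """A model fit failed to converge (e.g. complete separation in Cox)."""
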