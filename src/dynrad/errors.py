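"""Exception hierarchy for the dynrad pipeline.

Every stage raises a subclass of :class:`DynradError` so callers can catch
pipeline failures without masking programming errors.
"""


class DynradError(Exception):
    """Base class for all dynrad-specific failures."""


class GeometryError(DynradError):
    """Degenerate phantom geometry or mismatched image/mask shapes."""


class FlatImageError(DynradError):
    """Intensity rescaling requested on an image with zero dynamic range."""


class ParameterError(DynradError):
    """Invalid user-supplied parameter (negative noise std, duplicate levels...)."""


class EmptyROIError(DynradError):
    """A feature was requested on an empty region of interest."""


class DegenerateROIError(DynradError):
    """The ROI admits no valid texture-matrix entries (no pixel pairs / zones)."""


class MaskError(DynradError):
    """A mask volume contains values other than 0 and 1."""


class CompletenessError(DynradError):
    """The long-format feature table is missing cells required to build curves."""


class MissingReferenceError(DynradError):
    """No reference (zero-noise) curve exists for a subject+feature."""


class AlignmentError(DynradError):
    """Two curves to be compared have different lengths or identities."""


class InsufficientInstancesError(DynradError):
    """Fewer than two noise instances available for a pairwise score."""


class EmptyRankingError(DynradError):
    """All features of a subject were excluded; no ranking can be formed."""


class EmptyConsensusError(DynradError):
    """No feature survives exclusion in every subject."""


class InsufficientFramesError(DynradError):
    """A curve is shorter than the requested subsample length."""


class StratificationError(DynradError):
    """A class has too few subjects for the requested train/val/test counts."""


class TrainingError(DynradError):
    """Degenerate training data (e.g. a single class) for a decision tree."""


class PipelineError(DynradError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
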