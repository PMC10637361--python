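"""Exception hierarchy for tfusplan.

All package errors derive from :class:`TfusplanError` so callers can catch
one base class at pipeline boundaries.
"""


class TfusplanError(Exception):
    """Base class for all tfusplan errors."""


class FormatError(TfusplanError):
    """A file exists but is not in the expected format."""


class ValidationError(TfusplanError):
    """Inputs are well-formed but violate a documented contract."""


class DegenerateLandmarksError(ValidationError):
    """AC/PC landmarks coincide or are too close to define an axis."""


class NoOverlapError(TfusplanError):
    """The transformed moving image does not overlap the fixed image."""


class DesignMatrixRankError(ValidationError):
    """Gradient scheme does not span enough directions for a tensor fit."""


class OutOfBoundsError(TfusplanError):
    """A requested point lies outside the image grid."""


class EmptyBundleError(TfusplanError):
    """A streamline bundle or probability map contains nothing."""


class EmptyMaskError(TfusplanError):
    """A binary mask required to be non-empty is empty."""


class EmptyRecordError(TfusplanError):
    """All treatment points were filtered out of a record."""


class EmptySelectionError(TfusplanError):
    """A cohort condition selects zero patients (M == 0)."""


class UndefinedDiceError(TfusplanError):
    """Dice overlap of two empty masks is undefined."""


class StageError(TfusplanError):
    """A pipeline stage failed; carries the stage tag for the run report."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
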