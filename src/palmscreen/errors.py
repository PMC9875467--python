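"""Exception hierarchy for the palmscreen pipeline."""


class PalmscreenError(Exception):
    """Base class for all pipeline failures."""


class SegmentationError(PalmscreenError):
    """Raised when ROI segmentation produces an empty foreground."""

    def __init__(self, image_id: str, message: str = ""):
        self.image_id = image_id
        super().__init__(message or f"segmentation failed for image {image_id!r}: empty foreground")


class EmptyFilterError(PalmscreenError):
    """Raised when the L*/RGB pixel filter removes every ROI pixel."""

    def __init__(self, image_id: str = "<unknown>"):
        self.image_id = image_id
        super().__init__(f"pixel filter retained zero pixels for image {image_id!r}")


class StageError(PalmscreenError):
    """A pipeline stage failed; carries the stage name and offending artifact."""

    def __init__(self, stage: str, artifact: str, cause: Exception):
        self.stage = stage
        self.artifact = artifact
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on {artifact!r}: {cause}")
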