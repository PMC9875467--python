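"""Palm ROI extraction by grayscale triangle thresholding.

The triangle method (Zack's geometric construction) picks the gray level
maximizing the perpendicular distance between the histogram curve and the
straight line joining the histogram peak to the farthest non-empty tail
bin. It is well suited to strongly skewed/bimodal histograms such as a
bright palm on a dark background.

Coordinates are row-major, 0-based, top-left origin throughout.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage import measure

from .cohort import PalmImage
from .errors import SegmentationError

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights (R, G, B).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class RoiMask:
    """Boolean palm mask plus the gray threshold that produced it."""

    mask: np.ndarray  # H x W bool
    threshold_used: int

    def __post_init__(self):
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class RoiCrop:
    """A bounding-box crop of the palm with its (cropped) mask alongside.

    Pixels inside the box but outside the mask are flagged by ``mask`` so
    feature extraction can skip them.
    """

    pixels: np.ndarray  # h x w x 3 uint8
    mask: np.ndarray  # h x w bool
    patient_id: str = ""
    provenance: str = "original"
    transform_tag: str = ""

    @classmethod
    def full_frame(cls, image: PalmImage) -> "RoiCrop":
        """Treat the whole frame as ROI (every pixel retained by the mask)."""
        return cls(
            pixels=image.pixels,
            mask=np.ones(image.pixels.shape[:2], dtype=bool),
            patient_id=image.patient_id,
            provenance=image.provenance,
            transform_tag=image.transform_tag,
        )

    @property
    def image_id(self) -> str:
        return f"{self.patient_id}__{self.transform_tag}" if self.transform_tag else self.patient_id


def to_grayscale(image: PalmImage | np.ndarray) -> np.ndarray:
    """8-bit grayscale via BT.601 luma: round(0.299 R + 0.587 G + 0.114 B)."""
    pixels = image.pixels if isinstance(image, PalmImage) else np.asarray(image)
    gray = np.round(pixels.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def gray_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit grayscale raster."""
    return np.bincount(gray.ravel(), minlength=256)


def triangle_threshold(hist: np.ndarray) -> int:
    """Gray level maximizing perpendicular distance to the peak-tail chord.

    The chord joins the histogram peak (argmax count; first on ties) to the
    farthest non-empty bin. Candidate levels between them are scored by
    point-to-line distance; ties break toward the peak-distal side. A
    histogram with no triangle geometry (single occupied bin, or zero
    maximal distance as for a flat histogram) logs a degenerate-histogram
    warning and returns the farthest candidate.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or len(hist) != 256:
        raise ValueError("expected a 256-bin histogram")
    nz = np.flatnonzero(hist)
    if nz.size == 0:
        raise ValueError("empty histogram")
    peak = int(np.argmax(hist))
    if nz.size == 1:
        logger.warning("triangle_threshold: all mass in bin %d (degenerate)", peak)
        return peak
    # farthest occupied bin from the peak, on whichever side reaches farther
    tail = int(nz[0]) if peak - nz[0] >= nz[-1] - peak else int(nz[-1])
    lo, hi = (tail, peak) if tail < peak else (peak, tail)
    bins = np.arange(lo, hi + 1)
    # distance from (b, h[b]) to the line through (peak, h[peak]) and (tail, h[tail])
    dx, dy = tail - peak, hist[tail] - hist[peak]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (hist[bins] - hist[peak]) - dy * (bins - peak)) / norm
    best = dist.max()
    if best <= 0:
        logger.warning("triangle_threshold: flat geometry, degenerate histogram")
        return tail
    candidates = bins[dist == best]
    # tie-break toward the peak-distal side
    return int(candidates.max() if tail > peak else candidates.min())


def segment_palm(image: PalmImage, *, cleanup: bool = True) -> RoiMask:
    """Threshold the grayscale image and keep the palm component.

    Foreground polarity is auto-detected: the threshold class occupying the
    majority of the 1-pixel image border is taken as background. With
    ``cleanup`` (default), only the largest connected component is kept and
    its holes are filled, so background speckle never reaches the color
    features.
    """
    gray = to_grayscale(image)
    thr = triangle_threshold(gray_histogram(gray))
    above = gray > thr
    border = np.concatenate([above[0, :], above[-1, :], above[1:-1, 0], above[1:-1, -1]])
    fg = ~above if border.mean() > 0.5 else above
    if not fg.any():
        raise SegmentationError(image.image_id)
    if cleanup:
        labels = measure.label(fg, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
        fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        raise SegmentationError(image.image_id)
    return RoiMask(mask=fg, threshold_used=int(thr))


def crop_roi(image: PalmImage, roi: RoiMask) -> RoiCrop:
    """Crop to the tight bounding box of the mask, mask carried alongside."""
    mask = roi.mask
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask dimensions do not match image")
    if not mask.any():
        raise SegmentationError(image.image_id, f"empty mask for {image.image_id!r}")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return RoiCrop(
        pixels=image.pixels[r0:r1, c0:c1],
        mask=mask[r0:r1, c0:c1],
        patient_id=image.patient_id,
        provenance=image.provenance,
        transform_tag=image.transform_tag,
    )
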