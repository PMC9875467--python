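"""Pallor feature extraction from a segmented palm ROI.

The ROI's pixels are mapped to CIELAB; abnormally dark or bright pixels are
discarded by a joint L*/RGB band filter (minL < L* < maxL and each RGB
channel strictly inside (min_rgb, max_rgb)); the per-image feature vector
is then the arithmetic mean of a*, b* (offset encoding, a*+128) and of the
green channel G over the retained pixels, plus the a* standard deviation.

A simple heuristic label compares mean a* against the literature
discrimination thresholds: below 142 leans anemic, above 160 leans
non-anemic, the band in between is indeterminate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import color
from .errors import EmptyFilterError
from .segmentation import RoiCrop

A_STAR_LOW = 142.0  # offset encoding; mean a* below this leans anemic
A_STAR_HIGH = 160.0  # mean a* above this leans non-anemic


@dataclasses.dataclass(frozen=True)
class PixelFilter:
    """Joint lightness/RGB band retaining only pallor-informative pixels.

    Defaults exclude near-black shadow and near-white specular pixels; all
    bounds are strict (open interval) and configurable.
    """

    min_L: float = 10.0
    max_L: float = 96.0
    min_rgb: float = 10.0
    max_rgb: float = 245.0

    def __post_init__(self):
        if not (self.min_L < self.max_L and self.min_rgb < self.max_rgb):
            raise ValueError("filter bounds must satisfy min < max")


#: Filter that retains every pixel (identity).
IDENTITY_FILTER = PixelFilter(min_L=-1.0, max_L=101.0, min_rgb=-1.0, max_rgb=256.0)


@dataclasses.dataclass(frozen=True)
class PallorFeatures:
    """Per-image pallor feature vector.

    mean_a / mean_b are in the offset encoding (native value + 128) so that
    they are directly comparable with the 142/160 thresholds; mean_G is the
    8-bit green-channel mean; std_a is the a* standard deviation (identical
    in native and offset encodings).
    """

    mean_a: float
    mean_b: float
    mean_G: float
    std_a: float
    n_pixels_used: int

    def __post_init__(self):
        if self.n_pixels_used < 1:
            raise ValueError("a valid feature vector needs at least one retained pixel")

    def as_array(self, include_std_a: bool = False) -> np.ndarray:
        v = [self.mean_a, self.mean_b, self.mean_G]
        if include_std_a:
            v.append(self.std_a)
        return np.asarray(v, dtype=np.float64)


def apply_pixel_filter(
    lab: np.ndarray, rgb: np.ndarray, pixel_filter: PixelFilter, image_id: str = "<unknown>"
) -> np.ndarray:
    """Boolean keep-mask over aligned (N, 3) Lab and RGB pixel buffers.

    Retains pixels with min_L < L* < max_L and every RGB channel strictly
    inside (min_rgb, max_rgb); order is preserved by masking. Raises
    :class:`EmptyFilterError` if nothing survives.
    """
    lab = np.asarray(lab, dtype=np.float64)
    rgb = np.asarray(rgb, dtype=np.float64)
    if lab.shape != rgb.shape or lab.ndim != 2 or lab.shape[1] != 3:
        raise ValueError("lab and rgb buffers must be aligned (N, 3) arrays")
    keep = (lab[:, 0] > pixel_filter.min_L) & (lab[:, 0] < pixel_filter.max_L)
    keep &= np.all((rgb > pixel_filter.min_rgb) & (rgb < pixel_filter.max_rgb), axis=1)
    if not keep.any():
        raise EmptyFilterError(image_id)
    return keep


def compute_features(
    roi: RoiCrop, pixel_filter: PixelFilter = PixelFilter()
) -> PallorFeatures:
    """Mean a*, b*, G and std a* over mask pixels surviving the filter."""
    rgb = roi.pixels[roi.mask].astype(np.float64)
    if rgb.shape[0] == 0:
        raise EmptyFilterError(roi.image_id)
    lab = color.rgb_to_lab(rgb)
    keep = apply_pixel_filter(lab, rgb, pixel_filter, image_id=roi.image_id)
    lab, rgb = lab[keep], rgb[keep]
    return PallorFeatures(
        mean_a=float(color.a_to_offset(lab[:, 1].mean())),
        mean_b=float(color.a_to_offset(lab[:, 2].mean())),
        mean_G=float(rgb[:, 1].mean()),
        std_a=float(lab[:, 1].std()),
        n_pixels_used=int(keep.sum()),
    )


def a_star_heuristic(
    features: PallorFeatures, low: float = A_STAR_LOW, high: float = A_STAR_HIGH
) -> str:
    """Threshold heuristic on mean a* (offset encoding).

    < low -> "anemic_leaning"; > high -> "non_anemic_leaning"; otherwise
    "indeterminate".
    """
    if features.mean_a < low:
        return "anemic_leaning"
    if features.mean_a > high:
        return "non_anemic_leaning"
    return "indeterminate"


def features_table(
    crops: list[RoiCrop],
    labels: list[str] | None = None,
    pixel_filter: PixelFilter = PixelFilter(),
) -> pd.DataFrame:
    """Feature vectors for a batch of ROI crops as a tidy DataFrame."""
    rows = []
    for i, crop in enumerate(crops):
        f = compute_features(crop, pixel_filter)
        rows.append(
            {
                "patient_id": crop.patient_id,
                "provenance": crop.provenance,
                "transform_tag": crop.transform_tag,
                "mean_a": f.mean_a,
                "mean_b": f.mean_b,
                "mean_G": f.mean_G,
                "std_a": f.std_a,
                "n_pixels_used": f.n_pixels_used,
                "heuristic": a_star_heuristic(f),
                "label": labels[i] if labels is not None else "",
            }
        )
    return pd.DataFrame(rows)
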