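"""Dataset expansion by intensity-preserving geometric transforms.

The transform set is deliberately restricted to exact pixel permutations
(90/270 degree rotations, horizontal/vertical mirrors) plus a small
translation: none of them resample or rescale intensities, so per-image
color statistics — in particular the mean a* pallor signal — survive
augmentation. Cropping and Gaussian-noise augmentation are deliberately
absent because they change mean channel intensity.

Each original expands to exactly five views (rot90, rot270, flip_h,
flip_v, translate); the untransformed original is not a pool member, so a
cohort of N originals yields a pool of 5N augmented images.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import PalmImage
from .errors import PalmscreenError

DEFAULT_TRANSFORMS = ("rot90", "rot270", "flip_h", "flip_v", "translate")


@dataclasses.dataclass(frozen=True)
class AugmentSpec:
    """Ordered transform list plus translation offsets and edge policy."""

    transforms: tuple = DEFAULT_TRANSFORMS
    translate_dx: int = 8
    translate_dy: int = 8
    edge_policy: str = "reflect"  # reflect | wrap

    def __post_init__(self):
        if not self.transforms:
            raise ValueError("transform list must be non-empty")
        if len(set(self.transforms)) != len(self.transforms):
            raise ValueError("duplicate transforms")
        unknown = set(self.transforms) - set(DEFAULT_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        if self.edge_policy not in ("reflect", "wrap"):
            raise ValueError(f"unknown edge policy {self.edge_policy!r}")


def _derived(image: PalmImage, pixels: np.ndarray, tag: str) -> PalmImage:
    return PalmImage(
        patient_id=image.patient_id,
        pixels=np.ascontiguousarray(pixels),
        provenance="augmented",
        transform_tag=tag,
    )


def rotate(image: PalmImage, degrees: int) -> PalmImage:
    """Rotate by 90 or 270 degrees counter-clockwise (exact permutation)."""
    if degrees not in (90, 270):
        raise ValueError(f"only 90 and 270 degree rotations are supported, got {degrees}")
    k = 1 if degrees == 90 else 3
    return _derived(image, np.rot90(image.pixels, k=k), f"rot{degrees}")


def flip(image: PalmImage, axis: str) -> PalmImage:
    """Mirror horizontally (left-right) or vertically (top-bottom)."""
    if axis == "horizontal":
        return _derived(image, image.pixels[:, ::-1], "flip_h")
    if axis == "vertical":
        return _derived(image, image.pixels[::-1, :], "flip_v")
    raise ValueError(f"unknown flip axis {axis!r}")


def translate(image: PalmImage, dx: int, dy: int, edge_policy: str = "reflect") -> PalmImage:
    """Shift content by (dx, dy) pixels (x: columns right, y: rows down).

    The vacated margin is filled by the edge policy: ``wrap`` rolls pixels
    around (an exact permutation, conserving every channel statistic);
    ``reflect`` mirrors the content across the vacated edge.
    """
    h, w = image.pixels.shape[:2]
    bound = min(h, w) / 4
    if abs(dx) >= bound or abs(dy) >= bound:
        raise ValueError(f"translation ({dx}, {dy}) exceeds min(H, W)/4 = {bound}")
    if edge_policy == "wrap":
        out = np.roll(image.pixels, shift=(dy, dx), axis=(0, 1))
    elif edge_policy == "reflect":
        pad = max(abs(dx), abs(dy), 1)
        padded = np.pad(image.pixels, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        out = padded[pad - dy : pad - dy + h, pad - dx : pad - dx + w]
    else:
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    return _derived(image, out, "translate")


def _apply(image: PalmImage, tag: str, spec: AugmentSpec) -> PalmImage:
    if tag == "rot90":
        return rotate(image, 90)
    if tag == "rot270":
        return rotate(image, 270)
    if tag == "flip_h":
        return flip(image, "horizontal")
    if tag == "flip_v":
        return flip(image, "vertical")
    if tag == "translate":
        return translate(image, spec.translate_dx, spec.translate_dy, spec.edge_policy)
    raise ValueError(f"unknown transform {tag!r}")


def expand_dataset(images: list[PalmImage], spec: AugmentSpec = AugmentSpec()) -> list[PalmImage]:
    """Expand originals into the augmented pool (default 5 views each).

    Class labels travel with patient_id, which every view inherits, so
    group-aware splitting downstream remains possible.
    """
    if not images:
        raise ValueError("no original images to expand")
    pool: list[PalmImage] = []
    for image in images:
        for tag in spec.transforms:
            try:
                pool.append(_apply(image, tag, spec))
            except Exception as exc:  # noqa: BLE001 - re-raise with provenance
                raise PalmscreenError(
                    f"transform {tag!r} failed on image {image.image_id!r}: {exc}"
                ) from exc
    return pool
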