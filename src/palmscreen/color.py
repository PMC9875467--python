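"""sRGB <-> CIELAB conversion helpers (D65 reference white).

The pallor signal lives in the CIELAB a* (red-green) opponent channel:
well-perfused skin is redder (higher a*), pale skin sits closer to the
achromatic axis. Literature discrimination thresholds for palm pallor are
quoted in an *offset* 8-bit-style encoding, ``a_offset = a* + 128``, under
which "mean a* < 142" flags pallor and "mean a* > 160" flags normal
perfusion. Native signed CIELAB units and the offset encoding are both
supported here; conversion between them is a fixed +/-128 shift.

All transforms delegate to skimage.color, i.e. the standard
sRGB companding -> linear RGB -> XYZ (D65) -> CIELAB chain.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

#: Shift between native signed a*/b* units and the offset 8-bit-style encoding.
CHANNEL_OFFSET = 128.0


def a_to_offset(a_native: float | np.ndarray) -> float | np.ndarray:
    """Native signed a* (or b*) -> offset encoding (a* + 128)."""
    return a_native + CHANNEL_OFFSET


def a_from_offset(a_offset: float | np.ndarray) -> float | np.ndarray:
    """Offset-encoded a* (or b*) -> native signed CIELAB units."""
    return a_offset - CHANNEL_OFFSET


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB values to native CIELAB (L* in [0, 100]).

    Parameters
    ----------
    rgb : array, shape (..., 3)
        8-bit channel values in [0, 255]; integer or float dtype.

    Returns
    -------
    lab : float array, shape (..., 3)
        Columns L*, a*, b* in native signed units.
    """
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    if arr.ndim == 1:
        return _skcolor.rgb2lab(arr[np.newaxis, np.newaxis, :])[0, 0]
    if arr.ndim == 2:
        return _skcolor.rgb2lab(arr[:, np.newaxis, :])[:, 0, :]
    return _skcolor.rgb2lab(arr)


def lab_to_rgb(lab: np.ndarray, *, return_clipped: bool = False):
    """Convert native CIELAB to 8-bit sRGB, clamping out-of-gamut colors.

    Inverse of :func:`rgb_to_lab` up to 8-bit quantization. Colors outside
    the sRGB gamut are clamped to the gamut boundary; ``return_clipped=True``
    additionally returns a boolean mask of pixels that required clamping
    (detected by a reconversion check with tolerance 0.5 CIELAB units).
    """
    arr = np.asarray(lab, dtype=np.float64)
    squeeze = 0
    if arr.ndim == 1:
        arr = arr[np.newaxis, np.newaxis, :]
        squeeze = 2
    elif arr.ndim == 2:
        arr = arr[:, np.newaxis, :]
        squeeze = 1
    rgb01 = np.clip(_skcolor.lab2rgb(arr), 0.0, 1.0)
    rgb = np.round(rgb01 * 255.0).astype(np.uint8)
    if squeeze == 2:
        rgb = rgb[0, 0]
    elif squeeze == 1:
        rgb = rgb[:, 0, :]
    if not return_clipped:
        return rgb
    # out-of-gamut detection: an in-gamut color survives the round trip
    back = _skcolor.rgb2lab(rgb01)
    clipped = np.any(np.abs(back - arr) > 0.5, axis=-1)
    if squeeze == 2:
        clipped = bool(clipped[0, 0])
    elif squeeze == 1:
        clipped = clipped[:, 0]
    return rgb, clipped
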