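"""Vectorized RGB <-> HSL conversion.

The token classifier works in HSL space: hue carries the token color,
while saturation and luminance are used only to mask out grey, black and
white pixels. Hue is expressed in degrees on [0, 360) and is undefined
(NaN) for achromatic pixels (saturation = 0), which downstream masks drop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_hsl", "hsl_to_rgb"]


def rgb_to_hsl(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB image to (hue, saturation, luminance) planes.

    Parameters
    ----------
    image
        Array of shape (..., 3) with integer channels in [0, 255].

    Returns
    -------
    hue, saturation, luminance
        Float arrays of shape ``image.shape[:-1]``. Hue is in degrees on
        [0, 360) and NaN where the pixel is achromatic; saturation and
        luminance are on [0, 1].
    """
    arr = np.asarray(image, dtype=np.float64) / 255.0
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError("expected an array with a trailing RGB axis of size 3")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    c = mx - mn
    lum = (mx + mn) / 2.0

    sat = np.zeros_like(lum)
    chromatic = c > 0
    # 1 - |2L - 1| is strictly positive wherever c > 0
    sat[chromatic] = c[chromatic] / (1.0 - np.abs(2.0 * lum[chromatic] - 1.0))

    hue = np.full_like(lum, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / c, 6.0)
        hg = (b - r) / c + 2.0
        hb = (r - g) / c + 4.0
    is_r = chromatic & (mx == r)
    is_g = chromatic & (mx == g) & ~is_r
    is_b = chromatic & ~is_r & ~is_g
    hue[is_r] = hr[is_r]
    hue[is_g] = hg[is_g]
    hue[is_b] = hb[is_b]
    hue = hue * 60.0
    return hue, sat, lum


def hsl_to_rgb(hue, sat, lum) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsl`; accepts scalars or broadcastable arrays.

    NaN hue is treated as hue 0 (the pixel is grey anyway when sat = 0).
    Returns uint8 RGB with shape ``broadcast_shape + (3,)``.
    """
    hue, sat, lum = np.broadcast_arrays(
        np.asarray(hue, dtype=np.float64),
        np.asarray(sat, dtype=np.float64),
        np.asarray(lum, dtype=np.float64),
    )
    h = np.where(np.isnan(hue), 0.0, np.mod(hue, 360.0)) / 60.0
    c = (1.0 - np.abs(2.0 * lum - 1.0)) * sat
    x = c * (1.0 - np.abs(np.mod(h, 2.0) - 1.0))
    m = lum - c / 2.0

    zeros = np.zeros_like(c)
    sector = np.floor(h).astype(int) % 6
    # per-sector (r, g, b) before the lightness offset
    r = np.choose(sector, [c, x, zeros, zeros, x, c])
    g = np.choose(sector, [x, c, c, x, zeros, zeros])
    b = np.choose(sector, [zeros, zeros, x, c, c, x])
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
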