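"""Small JPEG/PNG load/save helpers around Pillow.

All pipeline functions operate on uint8 RGB numpy arrays of shape
(height, width, 3); these helpers are the only place file formats appear.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a JPEG/PNG file as a uint8 RGB array (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(image: np.ndarray, path: str | os.PathLike, quality: int = 95) -> Path:
    """Write a uint8 RGB array as JPEG or PNG, inferred from the suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    im = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        im.save(path, quality=quality)
    else:
        im.save(path)
    return path


def resize_bilinear(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Deterministic bilinear resample to exactly (height, width, 3)."""
    if width < 1 or height < 1:
        raise ValueError("target dimensions must be >= 1 pixel")
    im = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB")
    return np.asarray(im.resize((width, height), Image.BILINEAR), dtype=np.uint8)
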