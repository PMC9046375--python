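"""Portrait standardization.

Raw participant photographs vary in size, aspect ratio, orientation and
framing. This module converts them into fixed-size, fixed-aspect roster
portraits with an optional black border, driven entirely by coordinates
(quadrant clicks for rotation, bounding boxes for framing) so batches are
scriptable without a GUI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MalformedNameError, ValidationError
from .imgio import load_image, resize_bilinear, save_image

__all__ = [
    "StandardizationParams",
    "parse_photo_id",
    "rotate_quadrant",
    "adjust_bbox_to_aspect",
    "crop_standardize",
    "standardize_batch",
]


@dataclass(frozen=True)
class StandardizationParams:
    """Output geometry of a standardized portrait.

    size_out : output width in pixels.
    asr : aspect ratio, height / width, so the output is
        ``size_out x round(size_out * asr)`` pixels.
    border_px : width of the black frame painted on every side.
    pattern : filename extension of the raw photos (".jpg" or ".JPG" ...).
    start, stop : 1-based positions of the first and last character of the
        participant ID inside each filename.
    """

    size_out: int = 500
    asr: float = 1.25
    border_px: int = 0
    pattern: str = ".jpg"
    start: int = 1
    stop: int = 3

    def __post_init__(self):
        if self.size_out < 1:
            raise ValidationError("size_out must be >= 1")
        if self.asr <= 0:
            raise ValidationError("asr must be > 0")
        if self.border_px < 0:
            raise ValidationError("border_px must be >= 0")
        if self.start > self.stop or self.start < 1:
            raise ValidationError("need 1 <= start <= stop")

    @property
    def out_width(self) -> int:
        return self.size_out

    @property
    def out_height(self) -> int:
        return int(round(self.size_out * self.asr))


def parse_photo_id(filename: str, start: int, stop: int) -> str:
    """Extract the participant ID from a photo filename.

    IDs occupy fixed character positions ``start..stop`` (1-based) of the
    basename, e.g. ``("AOC.jpg", 1, 3) -> "AOC"``. The first ID character
    must be a letter.
    """
    stem = Path(filename).name
    if "." in stem:
        stem = stem[: stem.rindex(".")]
    if len(stem) < stop:
        raise MalformedNameError(
            f"filename {filename!r} has only {len(stem)} characters before the "
            f"extension; cannot take positions {start}..{stop}"
        )
    pid = stem[start - 1 : stop]
    if not pid[0].isalpha():
        raise ValidationError(f"ID {pid!r} must start with a letter")
    return pid


def _quadrant(click: tuple[float, float], width: int, height: int) -> int:
    """Number of 90-degree clockwise rotations for a quadrant click.

    Points exactly on a midline belong to the upper/left quadrant.
    """
    x, y = click
    if not (0 <= x <= width and 0 <= y <= height):
        raise ValidationError(f"click {click} outside image bounds {width}x{height}")
    left = x <= width / 2.0
    top = y <= height / 2.0
    if top and left:
        return 0
    if top:
        return 1  # upper-right: 90 degrees clockwise
    if left:
        return 3  # lower-left: 270 degrees clockwise
    return 2  # lower-right: 180 degrees


def rotate_quadrant(image: np.ndarray, click: tuple[float, float]) -> np.ndarray:
    """Rotate an image by the quadrant of a click: UL none, UR 90 CW,
    LR 180, LL 270 CW. Dimensions swap for the 90/270 cases."""
    k = _quadrant(click, image.shape[1], image.shape[0])
    # np.rot90 rotates counter-clockwise; negate for clockwise turns
    return np.ascontiguousarray(np.rot90(image, k=-k))


def adjust_bbox_to_aspect(
    bbox: tuple[float, float, float, float],
    asr: float,
    width: int,
    height: int,
) -> tuple[float, float, float, float]:
    """Expand a user bbox about its center to aspect ratio ``asr`` (h/w).

    The shorter-relative axis is enlarged (never shrunk), then the box is
    clamped to the image; expanding keeps everything the user selected.
    """
    x0, y0, x1, y1 = bbox
    x0, x1 = sorted((x0, x1))
    y0, y1 = sorted((y0, y1))
    x0, x1 = max(0.0, x0), min(float(width), x1)
    y0, y1 = max(0.0, y0), min(float(height), y1)
    bw, bh = x1 - x0, y1 - y0
    if bw <= 0 or bh <= 0:
        raise ValidationError("bounding box does not intersect the image")
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    if bh < asr * bw:
        bh = asr * bw
    else:
        bw = bh / asr
    x0, x1 = cx - bw / 2.0, cx + bw / 2.0
    y0, y1 = cy - bh / 2.0, cy + bh / 2.0
    # clamp by shifting first, then trimming if the image is simply too small
    if x0 < 0:
        x1 -= x0
        x0 = 0.0
    if y0 < 0:
        y1 -= y0
        y0 = 0.0
    if x1 > width:
        x0 -= x1 - width
        x1 = float(width)
    if y1 > height:
        y0 -= y1 - height
        y1 = float(height)
    x0, y0 = max(0.0, x0), max(0.0, y0)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        raise ValidationError("adjusted bounding box is degenerate")
    return (x0, y0, x1, y1)


def crop_standardize(
    image: np.ndarray,
    bbox: tuple[float, float, float, float],
    params: StandardizationParams,
) -> np.ndarray:
    """Crop ``bbox`` (aspect-adjusted), resample to the target size, and
    paint the black border. Output is always
    ``(round(size_out*asr), size_out, 3)``."""
    h, w = image.shape[:2]
    x0, y0, x1, y1 = adjust_bbox_to_aspect(bbox, params.asr, w, h)
    ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
    ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
    region = image[iy0:iy1, ix0:ix1]
    if region.size == 0:
        raise ValidationError("adjusted bounding box is degenerate")
    out = resize_bilinear(region, params.out_width, params.out_height)
    b = params.border_px
    if b > 0:
        out = out.copy()
        out[:b, :] = 0
        out[-b:, :] = 0
        out[:, :b] = 0
        out[:, -b:] = 0
    return out


def standardize_batch(
    input_dir: str | Path,
    output_dir: str | Path,
    params: StandardizationParams,
    id_range: Sequence[int] | None = None,
    id_names: Iterable[str] | None = None,
    spin: bool = True,
    rotations: Mapping[str, tuple[float, float]] | None = None,
    bboxes: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> dict[str, Path]:
    """Standardize every matching photo in ``input_dir``.

    Selection: ``id_range`` keeps only those 1-based positions in the
    sorted directory listing; ``id_names`` keeps only the given IDs. With
    ``spin`` off the rotation step is skipped entirely. ``rotations`` maps
    ID -> quadrant click; ``bboxes`` maps ID -> (x0, y0, x1, y1); a photo
    with no bbox entry is cropped full-frame. Outputs are written as
    ``<ID>.jpg``; reruns overwrite. Unreadable files are reported and
    skipped so one bad photo does not abort the batch.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    files = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.name.endswith(params.pattern)
    )
    if id_range is not None:
        wanted = set(id_range)
        files = [p for i, p in enumerate(files, start=1) if i in wanted]
    if id_names is not None:
        names = set(id_names)
        files = [
            p for p in files
            if parse_photo_id(p.name, params.start, params.stop) in names
        ]
    if not files:
        warnings.warn("no photographs selected; nothing to do", stacklevel=2)
        return {}

    written: dict[str, Path] = {}
    for path in files:
        pid = parse_photo_id(path.name, params.start, params.stop)
        try:
            img = load_image(path)
            if spin and rotations is not None and pid in rotations:
                img = rotate_quadrant(img, rotations[pid])
            bbox = (
                bboxes[pid]
                if bboxes is not None and pid in bboxes
                else (0.0, 0.0, float(img.shape[1]), float(img.shape[0]))
            )
            out = crop_standardize(img, bbox, params)
        except Exception as exc:  # noqa: BLE001 - batch continues per contract
            warnings.warn(f"skipping {path.name}: {exc}", stacklevel=2)
            continue
        written[pid] = save_image(out, output_dir / f"{pid}.jpg")
    return written
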