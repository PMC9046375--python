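"""Token-allocation classification by hue-density divergence.

A respondent marks ties by placing colored tokens on a photograph board.
For each recipient cell the classifier compares a control photograph
(blank board, no tokens) with the allocated photograph of the same board:

1. excise a border fraction of the cell (clothing/background guard),
2. Gaussian-blur to suppress high-contrast speckle,
3. optionally equalize the luminance histogram,
4. convert to HSL and drop pixels that are essentially grey
   (saturation below a floor) or essentially black/white
   (luminance outside a band),
5. form the normalized 1-degree-bin hue density of the surviving pixels
   and integrate it over the token color's hue interval.

A directed tie is coded when the hue mass in the token's interval rises
from blank to allocated by more than ``thresh``. With several token
colors the color with the largest divergence wins, provided it clears the
threshold.

The density estimator is a 1-degree-bin histogram, so the interval
integral is an exact bin sum; the spatial blur already provides the
smoothing a kernel density would add.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .color import hsl_to_rgb, rgb_to_hsl
from .errors import DegenerateCellError, PairingError, ValidationError
from .imgio import load_image, resize_bilinear, save_image
from .rectify import cell_bounds, extract_cells, rectify_board
from .survey import PanelLayout

__all__ = [
    "HueSpec",
    "ClassifierParams",
    "EdgeClassification",
    "rgb_to_hsl",
    "inspect_hue",
    "downsize",
    "preprocess_cell",
    "hue_density",
    "hue_mass",
    "classify_cell",
    "classify_board",
    "overlay_classification",
    "classify_directory",
]


@dataclass(frozen=True)
class HueSpec:
    """A named token color as a hue interval in degrees.

    If ``lower_hue > upper_hue`` the interval wraps through 0/360, e.g.
    (350, 10) covers red. Bounds may be given outside [0, 360) and are
    canonicalized, so (-10, 10) equals (350, 10).
    """

    color_label: str
    lower_hue: float
    upper_hue: float

    def __post_init__(self):
        object.__setattr__(self, "lower_hue", float(self.lower_hue) % 360.0)
        object.__setattr__(self, "upper_hue", float(self.upper_hue) % 360.0)
        if self.lower_hue == self.upper_hue:
            raise ValidationError("hue interval must have distinct bounds")

    @property
    def span(self) -> float:
        return (self.upper_hue - self.lower_hue) % 360.0

    def contains(self, hue: float | np.ndarray) -> np.ndarray:
        """Membership test, wrap-aware; NaN hue is never a member."""
        offset = np.mod(np.asarray(hue, dtype=np.float64) - self.lower_hue, 360.0)
        with np.errstate(invalid="ignore"):
            return offset <= self.span

    @property
    def display_rgb(self) -> tuple[int, int, int]:
        """Representative RGB (mid-interval hue) used for overlay markers."""
        mid = (self.lower_hue + self.span / 2.0) % 360.0
        return tuple(int(v) for v in hsl_to_rgb(mid, 0.9, 0.45))


@dataclass(frozen=True)
class ClassifierParams:
    """All tuning knobs of the cell-classification pipeline.

    thresh : minimum rise in hue mass (proportion scale) for a tie.
    lower_saturation_threshold : pixels at or below are treated as grey.
    lower/upper_luminance_threshold : pixels outside the open band are
        treated as black / white.
    iso_blur : Gaussian blur standard deviation in pixels; 0 disables.
    border_frac : fraction of width/height excised from every side.
    histogram_balancing : luminance-channel histogram equalization
        (hue-preserving) before masking.
    direction : warping mode handed to rectification when this parameter
        set drives a full-board run.

    The shipped defaults are tunable starting values, not calibrated
    constants.
    """

    thresh: float = 0.05
    lower_saturation_threshold: float = 0.10
    lower_luminance_threshold: float = 0.05
    upper_luminance_threshold: float = 0.95
    iso_blur: float = 3.0
    border_frac: float = 0.15
    histogram_balancing: bool = False
    direction: str = "backward"

    def __post_init__(self):
        if not 0.0 < self.thresh < 1.0:
            raise ValidationError("thresh must be in (0, 1)")
        if not 0.0 <= self.border_frac < 0.5:
            raise ValidationError("border_frac must be in [0, 0.5)")
        if self.iso_blur < 0:
            raise ValidationError("iso_blur must be >= 0")
        if not (
            0.0
            <= self.lower_luminance_threshold
            < self.upper_luminance_threshold
            <= 1.0
        ):
            raise ValidationError("luminance thresholds must satisfy lower < upper")


@dataclass(frozen=True)
class EdgeClassification:
    """One inferred directed tie: recipient, winning color, divergence."""

    aid: str
    color_label: str
    divergence: float


def inspect_hue(image: np.ndarray, point: tuple[int, int]) -> tuple[float, float, float]:
    """HSL of a single pixel (x, y) — a helper for picking hue thresholds
    from a real token photograph. No preprocessing is applied."""
    x, y = int(point[0]), int(point[1])
    h, w = image.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise ValidationError(f"point {point} outside image bounds {w}x{h}")
    hue, sat, lum = rgb_to_hsl(image[y, x])
    return float(hue), float(sat), float(lum)


def downsize(image: np.ndarray, scaler: float) -> np.ndarray:
    """Shrink an image by an integer-or-real factor >= 1 (bilinear).

    ``scaler=1`` returns the image unchanged; dimensions are divided by
    ``scaler`` and rounded.
    """
    if scaler < 1:
        raise ValidationError("scaler must be >= 1")
    if scaler == 1:
        return image
    h, w = image.shape[:2]
    return resize_bilinear(
        image, max(1, int(round(w / scaler))), max(1, int(round(h / scaler)))
    )


def _equalize_luminance(image: np.ndarray) -> np.ndarray:
    """Histogram-equalize the luminance channel, preserving hue."""
    hue, sat, lum = rgb_to_hsl(image)
    flat = lum.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, dtype=np.float64)
    ranks[order] = np.arange(1, len(flat) + 1)
    eq = (ranks / len(flat)).reshape(lum.shape)
    return hsl_to_rgb(hue, sat, eq)


def preprocess_cell(cell: np.ndarray, params: ClassifierParams) -> np.ndarray:
    """Border excision, blur, masking; returns the retained hue multiset.

    The result is a 1-D float array of hue degrees for every interior
    pixel that is chromatic enough and neither too dark nor too bright.
    """
    h, w = cell.shape[:2]
    bh = int(round(params.border_frac * h))
    bw = int(round(params.border_frac * w))
    interior = cell[bh : h - bh, bw : w - bw]
    if interior.size == 0:
        raise DegenerateCellError(
            f"cell {w}x{h} has no interior after excising border_frac={params.border_frac}"
        )
    interior = np.asarray(interior, dtype=np.float64)
    if params.iso_blur > 0:
        interior = ndimage.gaussian_filter(
            interior, sigma=(params.iso_blur, params.iso_blur, 0)
        )
    interior = np.clip(np.round(interior), 0, 255).astype(np.uint8)
    if params.histogram_balancing:
        interior = _equalize_luminance(interior)
    hue, sat, lum = rgb_to_hsl(interior)
    keep = (
        (sat > params.lower_saturation_threshold)
        & (lum > params.lower_luminance_threshold)
        & (lum < params.upper_luminance_threshold)
        & np.isfinite(hue)
    )
    return hue[keep]


def hue_density(hues: np.ndarray) -> np.ndarray:
    """Normalized 1-degree-bin density over [0, 360); all-zero if empty."""
    if len(hues) == 0:
        return np.zeros(360)
    bins = np.floor(np.asarray(hues, dtype=np.float64)).astype(int) % 360
    counts = np.bincount(bins, minlength=360).astype(np.float64)
    return counts / counts.sum()


def hue_mass(hues: np.ndarray, spec: HueSpec) -> float:
    """Fraction of retained hue mass inside the spec's interval.

    Computed from the normalized 1-degree-bin density: the sum of bins
    whose centers fall in the (possibly wrapping) interval. An empty
    multiset has mass 0, so a fully grey or black cell can never register
    a tie.
    """
    density = hue_density(hues)
    centers = np.arange(360, dtype=np.float64) + 0.5
    return float(density[spec.contains(centers)].sum())


def classify_cell(
    blank_cell: np.ndarray,
    game_cell: np.ndarray,
    spec: HueSpec,
    params: ClassifierParams,
) -> tuple[bool, float]:
    """Single-color decision for one recipient cell.

    The divergence is the signed rise in hue mass within the token's hue
    interval from the blank to the allocated photograph,
    ``delta = mass(game) - mass(blank)``; a tie is coded iff
    ``delta > params.thresh``.
    """
    delta = hue_mass(preprocess_cell(game_cell, params), spec) - hue_mass(
        preprocess_cell(blank_cell, params), spec
    )
    return delta > params.thresh, delta


def classify_board(
    blank_cells: Mapping[str, np.ndarray],
    game_cells: Mapping[str, np.ndarray],
    specs: Sequence[HueSpec],
    params: ClassifierParams,
) -> list[EdgeClassification]:
    """Classify every recipient cell of a board against up to five colors.

    For each recipient, the divergence is computed per color; the color
    with the largest divergence is emitted iff it exceeds ``thresh``.
    Recipients where no color clears the threshold yield no record.
    """
    if set(blank_cells) != set(game_cells):
        raise PairingError(
            "blank and game photographs cover different recipients: "
            f"{sorted(set(blank_cells) ^ set(game_cells))}"
        )
    if len(specs) > 5:
        raise ValidationError("at most five token colors are supported")
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            centers = np.arange(360) + 0.5
            if np.any(a.contains(centers) & b.contains(centers)):
                warnings.warn(
                    f"hue intervals of {a.color_label!r} and {b.color_label!r} overlap",
                    stacklevel=2,
                )
    edges: list[EdgeClassification] = []
    for aid in sorted(blank_cells):
        blank_hues = preprocess_cell(blank_cells[aid], params)
        game_hues = preprocess_cell(game_cells[aid], params)
        deltas = [
            hue_mass(game_hues, spec) - hue_mass(blank_hues, spec)
            for spec in specs
        ]
        best = int(np.argmax(deltas))
        if deltas[best] > params.thresh:
            edges.append(
                EdgeClassification(aid, specs[best].color_label, deltas[best])
            )
    return edges


def overlay_classification(
    rectified: np.ndarray,
    edges: Sequence[EdgeClassification],
    layout: PanelLayout,
    panel: str,
    specs: Sequence[HueSpec],
    marker_radius_frac: float = 0.12,
) -> np.ndarray:
    """Draw a colored disk at the center of every classified cell so the
    inferred ties can be checked visually against the board photograph."""
    spec_by_label = {s.color_label: s for s in specs}
    cells = layout.ids_for_panel(panel)
    pos_by_id = {pid: rc for rc, pid in cells.items()}
    h, w = rectified.shape[:2]
    row_bounds = cell_bounds(h, layout.n_rows)
    col_bounds = cell_bounds(w, layout.n_cols)
    out = rectified.copy()
    for edge in edges:
        if edge.aid not in pos_by_id:
            raise ValidationError(f"edge recipient {edge.aid!r} not on panel {panel}")
        if edge.color_label not in spec_by_label:
            raise ValidationError(f"unknown color label {edge.color_label!r}")
        r, c = pos_by_id[edge.aid]
        y0, y1 = row_bounds[r - 1]
        x0, x1 = col_bounds[c - 1]
        cy, cx = (y0 + y1) // 2, (x0 + x1) // 2
        radius = max(2, int(marker_radius_frac * min(y1 - y0, x1 - x0)))
        ys, xs = np.ogrid[:h, :w]
        disk = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
        out[disk] = spec_by_label[edge.color_label].display_rgb
    return out


def classify_directory(
    results_dir: str | Path,
    focal: str,
    game: str,
    panels: Sequence[str],
    layout: PanelLayout,
    specs: Sequence[HueSpec],
    params: ClassifierParams | None = None,
    corners: Mapping[str, Mapping[str, Sequence[Sequence[float]]]] | None = None,
    pre_processed: bool = False,
    scaler: float = 1.0,
    classified_dir: str | Path | None = None,
) -> list[EdgeClassification]:
    """File-level pipeline over a respondent's board photographs.

    Expects ``Blank_<focal>_<panel>.jpg`` and ``<game>_<focal>_<panel>.jpg``
    inside ``results_dir``. With ``pre_processed`` the photographs are
    assumed already cropped and squared and rectification is skipped;
    otherwise ``corners[condition][panel]`` must supply the four clicked
    corners per image. Annotated check images are written to
    ``classified_dir`` when given.
    """
    params = params or ClassifierParams()
    results_dir = Path(results_dir)
    edges: list[EdgeClassification] = []
    for panel in panels:
        boards = {}
        for condition in ("Blank", game):
            img = load_image(results_dir / f"{condition}_{focal}_{panel}.jpg")
            img = downsize(img, scaler)
            if not pre_processed:
                if corners is None:
                    raise ValidationError(
                        "corner quads are required unless pre_processed=True"
                    )
                img = rectify_board(
                    img, corners[condition][panel], direction=params.direction
                )
            boards[condition] = img
        blank_cells = extract_cells(
            boards["Blank"], layout.n_rows, layout.n_cols, layout, panel
        )
        game_cells = extract_cells(
            boards[game], layout.n_rows, layout.n_cols, layout, panel
        )
        panel_edges = classify_board(blank_cells, game_cells, list(specs), params)
        edges.extend(panel_edges)
        if classified_dir is not None:
            annotated = overlay_classification(
                boards[game], panel_edges, layout, panel, list(specs)
            )
            save_image(
                annotated,
                Path(classified_dir) / f"Classified_{game}_{focal}_{panel}.jpg",
            )
    return edges
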