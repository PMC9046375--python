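"""Synthetic rosters, boards and distortions with exact ground truth.

Every stage of the pipeline is testable without field photographs: this
module renders a deterministic portrait roster (with substantial
skin-tone-hue regions, the known hard case for warm-colored tokens),
composes blank/allocated board pairs with planted token disks, applies
known projective distortions, and replays the two validation experiments
of the token classifier — 26 rounds of 20 single-color tokens, and 26
rounds of 9 tokens in each of three colors, across a 39-recipient
two-panel board.

What the renders emulate: board geometry, token color and size, lighting
differences between the control and allocated exposures (a global
luminance offset), and camera perspective. What they do not emulate:
real faces, camera noise, specular highlights on laminated photos, or
shadows cast by tokens — so perfect recovery here demonstrates the
pipeline's correctness, not its field robustness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassifierParams, HueSpec, classify_board
from .color import hsl_to_rgb
from .errors import ValidationError
from .imgio import save_image
from .rectify import estimate_homography, extract_cells, rectify_board, warp_image
from .survey import PanelLayout, layout_panels, layout_to_frame, seeded_order

__all__ = [
    "GREEN", "NAVY", "PURPLE", "PAINT_HUES",
    "FixtureSpec", "GroundTruth", "ExperimentResult",
    "roster_ids", "render_roster", "render_board",
    "render_board_pair", "distort", "run_validation_experiment",
    "distortion_robustness", "write_fixture_project",
]

# Token colors used throughout: cool hues, which are easy to separate
# from skin tones; the interval is what the classifier integrates over,
# the paint hue is what the fixture renders.
GREEN = HueSpec("green", 100, 140)
NAVY = HueSpec("navy", 200, 260)
PURPLE = HueSpec("purple", 260, 300)
PAINT_HUES = {"green": 120.0, "navy": 230.0, "purple": 280.0}

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class FixtureSpec:
    """Study-design parameters of the synthetic data.

    Defaults reproduce the validation design: 39 recipients on two 4x5
    panels. ``token_radius`` is a fraction of the smaller cell dimension;
    ``lighting_jitter`` is the +/- luminance offset (on [0, 1]) between
    exposures; ``distortion_jitter`` is the maximum per-corner
    displacement in pixels of the projective warp.
    """

    n_recipients: int = 39
    n_panels: int = 2
    n_rows: int = 4
    n_cols: int = 5
    cell_width: int = 64
    cell_height: int = 80
    token_radius: float = 0.18
    lighting_jitter: float = 0.02
    distortion_jitter: float = 18.0
    seed: int = 2021
    token_colors: tuple[HueSpec, ...] = (GREEN, NAVY, PURPLE)

    def __post_init__(self):
        if not 0.0 < self.token_radius < 0.5:
            raise ValidationError("token_radius must be in (0, 0.5)")
        if self.n_recipients > self.n_panels * self.n_rows * self.n_cols:
            raise ValidationError("roster exceeds panel capacity")


@dataclass(frozen=True)
class GroundTruth:
    """Exact truth for one rendered round: the focal, the planted
    allocation (AID -> color label), and, once distorted, the true corner
    quad of each warped image."""

    focal: str
    allocation: dict[str, str]
    quads: dict[str, list[list[float]]] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentResult:
    """Tallies of a validation run against ground truth."""

    ties_recovered: int
    ties_planted: int
    false_positives: int
    empty_cells: int
    color_confusions: int


def roster_ids(n: int) -> list[str]:
    """Deterministic three-character IDs, letter-first (AA0, BB1, ...)."""
    return [f"{_ALPHA[i % 26]}{_ALPHA[(i // 26) % 26]}{i % 10}" for i in range(n)]


def _render_portrait(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    """One synthetic portrait: low-saturation backdrop, skin-hue face
    ellipse, dark hair band, warm-hued shirt. Warm (skin-range) hues are
    deliberately abundant to stress warm-token confusion."""
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = hsl_to_rgb(rng.uniform(0, 360), rng.uniform(0.0, 0.06),
                        rng.uniform(0.55, 0.8))
    ys, xs = np.mgrid[0:height, 0:width]
    # shirt: lower quarter, warm hue
    shirt_top = int(height * rng.uniform(0.70, 0.78))
    img[shirt_top:] = hsl_to_rgb(rng.uniform(0, 60), rng.uniform(0.25, 0.5),
                                 rng.uniform(0.3, 0.55))
    # face: central ellipse in the skin-tone hue band
    cx, cy = width / 2 + rng.uniform(-2, 2), height * 0.42 + rng.uniform(-3, 3)
    ax, ay = width * rng.uniform(0.30, 0.36), height * rng.uniform(0.30, 0.34)
    face = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    img[face] = hsl_to_rgb(rng.uniform(12, 38), rng.uniform(0.35, 0.55),
                           rng.uniform(0.45, 0.68))
    # hair: cap above the face
    hair = (((xs - cx) / (ax * 1.05)) ** 2
            + ((ys - cy) / (ay * 1.05)) ** 2 <= 1.0) & (ys < cy - ay * 0.35)
    img[hair] = hsl_to_rgb(rng.uniform(15, 35), rng.uniform(0.2, 0.4),
                           rng.uniform(0.08, 0.2))
    return img


def render_roster(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """Deterministic portrait per roster ID (seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    return {
        pid: _render_portrait(rng, spec.cell_width, spec.cell_height)
        for pid in roster_ids(spec.n_recipients)
    }


def _apply_lighting(image: np.ndarray, rng: np.random.Generator,
                    jitter: float) -> np.ndarray:
    """Global luminance offset: equal shift of all channels, which leaves
    hue untouched — exactly the nuisance the blank/game comparison must
    absorb."""
    delta = rng.uniform(-jitter, jitter) * 255.0
    return np.clip(image.astype(np.float64) + delta, 0, 255).astype(np.uint8)


def render_board(
    spec: FixtureSpec,
    layout: PanelLayout,
    panel: str,
    portraits: Mapping[str, np.ndarray],
    allocation: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Compose one panel image; plant a token disk per allocated recipient.

    Tokens are filled disks at the cell center (small positional jitter),
    painted at the color's paint hue with a small hue jitter, and sized by
    ``spec.token_radius``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    cw, ch = spec.cell_width, spec.cell_height
    board = np.full((spec.n_rows * ch, spec.n_cols * cw, 3), 235, dtype=np.uint8)
    cells = layout.ids_for_panel(panel)
    labels = {s.color_label for s in spec.token_colors}
    for (r, c), pid in sorted(cells.items()):
        y0, x0 = (r - 1) * ch, (c - 1) * cw
        board[y0 : y0 + ch, x0 : x0 + cw] = portraits[pid]
        if allocation and pid in allocation:
            color = allocation[pid]
            if color not in labels:
                raise ValidationError(f"allocation color {color!r} not in spec")
            radius = spec.token_radius * min(cw, ch)
            cx = x0 + cw / 2 + rng.uniform(-0.04, 0.04) * cw
            cy = y0 + ch / 2 + rng.uniform(-0.04, 0.04) * ch
            ys, xs = np.mgrid[0 : board.shape[0], 0 : board.shape[1]]
            disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
            hue = PAINT_HUES[color] + rng.uniform(-3, 3)
            board[disk] = hsl_to_rgb(hue, 0.85, 0.45)
    return board


def render_board_pair(
    spec: FixtureSpec,
    layout: PanelLayout,
    panel: str,
    allocation: Mapping[str, str],
    portraits: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Blank (control) and allocated exposures of the same panel; the two
    differ by the planted tokens plus independent lighting jitter."""
    blank = render_board(spec, layout, panel, portraits, allocation=None, rng=rng)
    game = render_board(spec, layout, panel, portraits, allocation=allocation, rng=rng)
    return (
        _apply_lighting(blank, rng, spec.lighting_jitter),
        _apply_lighting(game, rng, spec.lighting_jitter),
    )


def distort(
    image: np.ndarray,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a random projective warp with known corners.

    The board is embedded in a slightly larger canvas with each corner
    displaced by at most ``spec.distortion_jitter`` px; the exact corner
    quad is returned so rectification can be tested against truth. Zero
    jitter is the identity warp.
    """
    rng = rng or np.random.default_rng(spec.seed)
    h, w = image.shape[:2]
    j = spec.distortion_jitter
    margin = int(np.ceil(j))
    base = np.array(
        [[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]
    ) + margin
    if j == 0:
        return image.copy(), base - margin
    for _ in range(100):
        quad = base + rng.uniform(-j, j, size=(4, 2))
        try:
            H = estimate_homography(quad, w, h)
        except Exception:
            continue
        canvas = (w + 2 * margin, h + 2 * margin)
        warped = warp_image(image, np.linalg.inv(H), canvas, direction="backward")
        return warped, quad
    raise ValidationError("could not draw a convex corner quad; reduce jitter")


def _plant_allocation(
    rng: np.random.Generator,
    ids: Sequence[str],
    focal: str,
    tokens_per_color: Mapping[str, int],
) -> dict[str, str]:
    """Place tokens on distinct recipients, never on the focal's own cell."""
    candidates = [i for i in ids if i != focal]
    total = sum(tokens_per_color.values())
    chosen = rng.choice(len(candidates), size=total, replace=False)
    allocation: dict[str, str] = {}
    k = 0
    for color, count in tokens_per_color.items():
        for _ in range(count):
            allocation[candidates[chosen[k]]] = color
            k += 1
    return allocation


def run_validation_experiment(
    mode: str,
    spec: FixtureSpec | None = None,
    params: ClassifierParams | None = None,
    n_rounds: int = 26,
    distorted: bool = False,
    seed: int | None = None,
) -> ExperimentResult:
    """Replay a perfect-recovery validation experiment against truth.

    mode "single_color": 20 green tokens per round; mode "three_color":
    9 tokens of each of navy, purple and green per round. Each round
    renders a blank/allocated pair per panel (optionally distorts both
    with independent random warps and rectifies them from the true
    corners), extracts recipient cells, classifies, and tallies recovered
    ties, false positives on empty cells, and cross-color confusions.
    """
    spec = spec or FixtureSpec()
    params = params or ClassifierParams()
    if mode == "single_color":
        tokens_per_color = {"green": 20}
        specs = [GREEN]
    elif mode == "three_color":
        tokens_per_color = {"navy": 9, "purple": 9, "green": 9}
        specs = [GREEN, NAVY, PURPLE]
    else:
        raise ValidationError("mode must be 'single_color' or 'three_color'")

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = roster_ids(spec.n_recipients)
    layout = layout_panels(
        seeded_order(ids, spec.seed), spec.n_panels, spec.n_rows, spec.n_cols
    )
    portraits = render_roster(spec)

    recovered = planted = false_pos = empty = confused = 0
    for rnd in range(n_rounds):
        focal = ids[rnd % len(ids)]
        allocation = _plant_allocation(rng, ids, focal, tokens_per_color)
        planted += len(allocation)
        empty += spec.n_recipients - len(allocation)

        edges: dict[str, str] = {}
        for panel in layout.panels:
            blank, game = render_board_pair(
                spec, layout, panel, allocation, portraits, rng
            )
            if distorted:
                processed = []
                for img in (blank, game):
                    warped, quad = distort(img, spec, rng)
                    processed.append(
                        rectify_board(warped, quad, direction=params.direction)
                    )
                blank, game = processed
            blank_cells = extract_cells(blank, spec.n_rows, spec.n_cols, layout, panel)
            game_cells = extract_cells(game, spec.n_rows, spec.n_cols, layout, panel)
            for e in classify_board(blank_cells, game_cells, specs, params):
                edges[e.aid] = e.color_label

        for aid, color in edges.items():
            if aid not in allocation:
                false_pos += 1
            elif allocation[aid] == color:
                recovered += 1
            else:
                confused += 1
    return ExperimentResult(recovered, planted, false_pos, empty, confused)


def distortion_robustness(
    spec: FixtureSpec | None = None,
    params: ClassifierParams | None = None,
    n_rounds: int = 5,
    seed: int | None = None,
) -> tuple[int, int]:
    """Count rounds where rectified-after-distortion classification yields
    an edge list identical to classifying the flat render directly.

    Each round plants a 20-token single-color allocation, renders the
    board pairs once, classifies them as-is, then independently warps
    blank and game exposures with random known corner quads, rectifies
    from those corners and classifies again. Returns
    ``(identical_rounds, n_rounds)``.
    """
    spec = spec or FixtureSpec()
    params = params or ClassifierParams()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ids = roster_ids(spec.n_recipients)
    layout = layout_panels(
        seeded_order(ids, spec.seed), spec.n_panels, spec.n_rows, spec.n_cols
    )
    portraits = render_roster(spec)
    identical = 0
    for rnd in range(n_rounds):
        focal = ids[rnd % len(ids)]
        allocation = _plant_allocation(rng, ids, focal, {"green": 20})
        flat_edges: dict[str, str] = {}
        warped_edges: dict[str, str] = {}
        for panel in layout.panels:
            blank, game = render_board_pair(
                spec, layout, panel, allocation, portraits, rng
            )
            for target, images in (
                (flat_edges, (blank, game)),
                (warped_edges, tuple(
                    rectify_board(*distort(img, spec, rng), direction=params.direction)
                    for img in (blank, game)
                )),
            ):
                cells = [
                    extract_cells(img, spec.n_rows, spec.n_cols, layout, panel)
                    for img in images
                ]
                for e in classify_board(cells[0], cells[1], [GREEN], params):
                    target[e.aid] = e.color_label
        if flat_edges == warped_edges:
            identical += 1
    return identical, n_rounds


def write_fixture_project(
    out_dir: str | Path,
    spec: FixtureSpec | None = None,
    game: str = "Friends",
    n_rounds: int = 1,
    distorted: bool = False,
) -> Path:
    """Emit a full on-disk fixture: Blank_/<game>_ board photos for each
    round's focal, ``layout.csv`` and ``truth.json``, in the directory
    layout the file-level pipeline consumes end-to-end."""
    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    photos = out_dir / "ResultsPhotos"
    photos.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ids = roster_ids(spec.n_recipients)
    layout = layout_panels(
        seeded_order(ids, spec.seed), spec.n_panels, spec.n_rows, spec.n_cols
    )
    portraits = render_roster(spec)
    layout_to_frame(layout).to_csv(out_dir / "layout.csv", index=False)

    truth = []
    for rnd in range(n_rounds):
        focal = ids[rnd % len(ids)]
        allocation = _plant_allocation(rng, ids, focal, {"green": 20})
        gt = GroundTruth(focal=focal, allocation=allocation)
        quads: dict[str, list[list[float]]] = {}
        for panel in layout.panels:
            blank, gameimg = render_board_pair(
                spec, layout, panel, allocation, portraits, rng
            )
            for condition, img in (("Blank", blank), (game, gameimg)):
                if distorted:
                    img, quad = distort(img, spec, rng)
                    quads[f"{condition}_{panel}"] = quad.tolist()
                save_image(img, photos / f"{condition}_{focal}_{panel}.jpg")
        truth.append(
            {"focal": gt.focal, "allocation": gt.allocation, "quads": quads}
        )
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir
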