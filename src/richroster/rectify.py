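"""Projective rectification of photographed game boards.

A hand-held photograph of a board is rotated, skewed and sheared. Four
corner clicks (top-left, top-right, bottom-right, bottom-left, in that
order) define a projective transform that maps the board back onto an
upright rectangle; the rectified array is then cut into the per-recipient
photo cells.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateGeometryError, ValidationError
from .survey import PanelLayout

__all__ = [
    "validate_quad",
    "estimate_homography",
    "apply_homography",
    "warp_image",
    "rectify_board",
    "cell_bounds",
    "extract_cells",
]


def validate_quad(quad) -> np.ndarray:
    """Check a 4x2 corner quad is convex and in TL, TR, BR, BL click order.

    Convexity and orientation are tested by the signs of successive edge
    cross-products; a mis-ordered click sequence is rejected, not reordered.
    """
    q = np.asarray(quad, dtype=np.float64)
    if q.shape != (4, 2):
        raise ValidationError("corner quad must be four (x, y) points")
    cross = []
    for i in range(4):
        a = q[(i + 1) % 4] - q[i]
        b = q[(i + 2) % 4] - q[(i + 1) % 4]
        cross.append(a[0] * b[1] - a[1] * b[0])
    cross = np.asarray(cross)
    if np.any(np.isclose(cross, 0.0)):
        raise DegenerateGeometryError("three corner points are collinear")
    if not (np.all(cross > 0) or np.all(cross < 0)):
        raise DegenerateGeometryError("corner quad is not convex in click order")
    # In image coordinates (y down), TL->TR->BR->BL runs clockwise on
    # screen, which is positive orientation.
    if cross[0] < 0:
        raise DegenerateGeometryError(
            "corners must be clicked top-left, top-right, bottom-right, "
            "bottom-left"
        )
    return q


def estimate_homography(quad, out_w: int, out_h: int) -> np.ndarray:
    """Homography mapping the clicked quad onto the output rectangle.

    Solves the 8-unknown direct linear system from the four point
    correspondences quad[i] -> ((0,0), (out_w,0), (out_w,out_h), (0,out_h))
    exactly; the result is normalized so H[2, 2] = 1.
    """
    src = validate_quad(quad)
    dst = np.array(
        [[0.0, 0.0], [out_w, 0.0], [out_w, out_h], [0.0, out_h]]
    )
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i] = u
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"degenerate corner geometry: {exc}") from exc
    return np.append(h, 1.0).reshape(3, 3)


def apply_homography(H: np.ndarray, points) -> np.ndarray:
    """Map an (n, 2) array of points through a 3x3 homography."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    hom = np.hstack([pts, np.ones((len(pts), 1))]) @ np.asarray(H).T
    return hom[:, :2] / hom[:, 2:3]


def warp_image(
    image: np.ndarray,
    H: np.ndarray,
    out_dims: tuple[int, int],
    direction: str = "backward",
) -> np.ndarray:
    """Warp an image through a homography mapping source -> output coords.

    backward (default): every output pixel is sampled from the source at
    H^-1 (x, y) with bilinear interpolation — slower, high quality.
    forward: every source pixel is splatted onto its nearest output cell —
    fast, but may leave holes; holes and out-of-source samples are black.
    """
    H = np.asarray(H, dtype=np.float64)
    if abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateGeometryError("homography is singular")
    out_w, out_h = int(out_dims[0]), int(out_dims[1])
    img = np.asarray(image, dtype=np.uint8)

    if direction == "backward":
        xs, ys = np.meshgrid(
            np.arange(out_w, dtype=np.float64),
            np.arange(out_h, dtype=np.float64),
        )
        Hinv = np.linalg.inv(H)
        denom = Hinv[2, 0] * xs + Hinv[2, 1] * ys + Hinv[2, 2]
        sx = (Hinv[0, 0] * xs + Hinv[0, 1] * ys + Hinv[0, 2]) / denom
        sy = (Hinv[1, 0] * xs + Hinv[1, 1] * ys + Hinv[1, 2]) / denom
        out = np.empty((out_h, out_w, 3), dtype=np.uint8)
        for ch in range(3):
            out[..., ch] = ndimage.map_coordinates(
                img[..., ch].astype(np.float64),
                [sy, sx],
                order=1,
                mode="constant",
                cval=0.0,
            ).round()
        return out

    if direction == "forward":
        h, w = img.shape[:2]
        xs, ys = np.meshgrid(
            np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64)
        )
        denom = H[2, 0] * xs + H[2, 1] * ys + H[2, 2]
        tx = np.rint((H[0, 0] * xs + H[0, 1] * ys + H[0, 2]) / denom).astype(int)
        ty = np.rint((H[1, 0] * xs + H[1, 1] * ys + H[1, 2]) / denom).astype(int)
        keep = (tx >= 0) & (tx < out_w) & (ty >= 0) & (ty < out_h)
        out = np.zeros((out_h, out_w, 3), dtype=np.uint8)
        out[ty[keep], tx[keep]] = img[ys[keep].astype(int), xs[keep].astype(int)]
        return out

    raise ValidationError(f"direction must be 'forward' or 'backward', got {direction!r}")


def rectify_board(
    image: np.ndarray,
    quad,
    out_dims: tuple[int, int] | None = None,
    direction: str = "backward",
) -> np.ndarray:
    """Rectify a board photo from its four clicked corners.

    Output size defaults to the bounding box of the clicked quad, which
    preserves approximate scale; pass ``out_dims`` to override.
    """
    q = validate_quad(quad)
    if out_dims is None:
        out_dims = (
            int(round(q[:, 0].max() - q[:, 0].min())),
            int(round(q[:, 1].max() - q[:, 1].min())),
        )
    H = estimate_homography(q, out_dims[0], out_dims[1])
    return warp_image(image, H, out_dims, direction=direction)


def cell_bounds(extent: int, n: int) -> list[tuple[int, int]]:
    """Split ``extent`` pixels into ``n`` contiguous runs with boundaries at
    round(k * extent / n): full coverage, no overlap, even when ``extent``
    is not divisible by ``n``."""
    edges = [int(round(k * extent / n)) for k in range(n + 1)]
    return [(edges[k], edges[k + 1]) for k in range(n)]


def extract_cells(
    rectified: np.ndarray,
    n_rows: int,
    n_cols: int,
    layout: PanelLayout,
    panel: str,
) -> dict[str, np.ndarray]:
    """Cut a rectified panel image into its grid and bind cells to IDs.

    Returns ID -> cell image for occupied cells only; empty grid cells
    produce no entry.
    """
    cells = layout.ids_for_panel(panel)  # raises for unknown panel
    h, w = rectified.shape[:2]
    row_bounds = cell_bounds(h, n_rows)
    col_bounds = cell_bounds(w, n_cols)
    out: dict[str, np.ndarray] = {}
    for (r, c), pid in cells.items():
        y0, y1 = row_bounds[r - 1]
        x0, x1 = col_bounds[c - 1]
        out[pid] = rectified[y0:y1, x0:x1]
    return out
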