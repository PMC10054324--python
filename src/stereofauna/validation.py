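"""Checkerboard-based validation of stereo size measurements.

A low reprojection error alone does not guarantee accurate *size*
measurements, so the rig is validated against a target of known geometry: a
checkerboard of 9x8 squares with a 50 mm pitch held at working distances.
The procedure:

1. detect (here: ingest) the inner corners of the board in each image pair,
2. triangulate each corner's 3D position from its stereo correspondence,
3. for every corner, compute the 3D distance to all other corners on the
   same horizontal or vertical board line,
4. compare each measured distance to its known value — the index gap times
   the square size — and report the horizontal and vertical errors.

Summarizing the per-image errors against the board's recording distance
exposes the characteristic growth of stereo error with depth
(depth error scales like z^2 / (focal * baseline) for fixed pixel noise).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RectifiedRig, triangulate

logger = logging.getLogger(__name__)

__all__ = ["BoardSpec", "BoardImageErrors", "BoardErrorReport",
           "board_errors", "error_vs_distance"]


@dataclass(frozen=True)
class BoardSpec:
    """Checkerboard geometry: squares and metric pitch."""

    squares_x: int = 9
    squares_y: int = 8
    square_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.squares_x < 2 or self.squares_y < 2:
            raise ValueError("board needs at least 2x2 squares")
        if self.square_mm <= 0:
            raise ValueError("square size must be positive")

    @property
    def corners_x(self) -> int:
        return self.squares_x - 1

    @property
    def corners_y(self) -> int:
        return self.squares_y - 1


@dataclass
class BoardImageErrors:
    """Error summary for one stereo image pair of the board."""

    image_id: str
    mean_horizontal_mm: float
    mean_vertical_mm: float
    mean_distance_mm: float
    n_corners: int
    n_horizontal_pairs: int
    n_vertical_pairs: int


@dataclass
class BoardErrorReport:
    """Per-image and aggregate horizontal/vertical measurement errors."""

    images: list
    mean_horizontal_mm: float
    mean_vertical_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(i) for i in self.images])


def _image_errors(image_id, left_px, right_px, spec: BoardSpec,
                  rect: RectifiedRig) -> BoardImageErrors | None:
    """Errors for one image pair; corner arrays are (ny, nx, 2), NaN = unseen."""
    left_px = np.asarray(left_px, dtype=float)
    right_px = np.asarray(right_px, dtype=float)
    ny, nx = spec.corners_y, spec.corners_x
    if left_px.shape != (ny, nx, 2) or right_px.shape != (ny, nx, 2):
        raise ValueError(f"corner grids must have shape ({ny}, {nx}, 2)")
    visible = (np.all(np.isfinite(left_px), axis=2)
               & np.all(np.isfinite(right_px), axis=2))
    if visible.sum() < 2:
        logger.info("board image %s skipped: fewer than 2 corners visible",
                    image_id)
        return None
    pts3d = np.full((ny, nx, 3), np.nan)
    lp = rect.raw_to_rectified("left", left_px[visible])
    rp = rect.raw_to_rectified("right", right_px[visible])
    pts3d[visible] = triangulate(rect, lp, rp)

    def _pair_errors(line_points, line_visible):
        errs = []
        idx = [i for i in range(len(line_visible)) if line_visible[i]]
        for a, b in itertools.combinations(idx, 2):
            expected = (b - a) * spec.square_mm
            measured = np.linalg.norm(line_points[b] - line_points[a])
            errs.append(abs(measured - expected))
        return errs

    horiz = []
    for j in range(ny):  # corners sharing a board row
        horiz += _pair_errors(pts3d[j], visible[j])
    vert = []
    for i in range(nx):  # corners sharing a board column
        vert += _pair_errors(pts3d[:, i], visible[:, i])
    dist = float(np.mean(np.linalg.norm(pts3d[visible], axis=1)))
    return BoardImageErrors(
        image_id=str(image_id),
        mean_horizontal_mm=float(np.mean(horiz)) if horiz else float("nan"),
        mean_vertical_mm=float(np.mean(vert)) if vert else float("nan"),
        mean_distance_mm=dist, n_corners=int(visible.sum()),
        n_horizontal_pairs=len(horiz), n_vertical_pairs=len(vert))


def board_errors(corner_pairs, spec: BoardSpec, rect: RectifiedRig) -> BoardErrorReport:
    """Run the four-step validation over a set of stereo corner observations.

    ``corner_pairs`` is an iterable of ``(image_id, left_px, right_px)``
    with (ny, nx, 2) raw-pixel corner grids (NaN rows mark unobserved
    corners). Pair errors are averaged uniformly (no weighting by index
    gap). Images with fewer than two stereo-visible corners are skipped.
    """
    images = []
    for image_id, lp, rp in corner_pairs:
        res = _image_errors(image_id, lp, rp, spec, rect)
        if res is not None:
            images.append(res)
    if not images:
        raise ValueError("no usable board images")
    h = [i.mean_horizontal_mm for i in images if np.isfinite(i.mean_horizontal_mm)]
    v = [i.mean_vertical_mm for i in images if np.isfinite(i.mean_vertical_mm)]
    return BoardErrorReport(images=images,
                            mean_horizontal_mm=float(np.mean(h)) if h else float("nan"),
                            mean_vertical_mm=float(np.mean(v)) if v else float("nan"))


def error_vs_distance(report: BoardErrorReport, bin_width_mm: float = 500.0) -> pd.DataFrame:
    """Bin per-image errors by recording distance.

    Returns a DataFrame with one row per non-empty bin, sorted ascending:
    bin center, count, mean/sd of horizontal and vertical errors.
    """
    df = report.to_frame()
    if df.empty:
        raise ValueError("empty report")
    bins = np.floor(df["mean_distance_mm"] / bin_width_mm).astype(int)
    rows = []
    for b in sorted(bins.unique()):
        sub = df[bins == b]
        rows.append({
            "bin_center_mm": (b + 0.5) * bin_width_mm,
            "n_images": len(sub),
            "horizontal_mean_mm": sub["mean_horizontal_mm"].mean(),
            "horizontal_sd_mm": sub["mean_horizontal_mm"].std(ddof=0),
            "vertical_mean_mm": sub["mean_vertical_mm"].mean(),
            "vertical_sd_mm": sub["mean_vertical_mm"].std(ddof=0),
        })
    return pd.DataFrame(rows)
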