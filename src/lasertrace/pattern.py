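"""Physical model of the zig-zag target pattern and pixel<->mm calibration.

The clinical target is a 1 mm thick black zig-zag center line of 1 m total
trace length printed on an A3 board (420 x 297 mm, landscape).  The exact
apex layout of the printed board is a free parameter here: the pattern is a
parameterized model whose defaults honor the printed constraints (board size,
line width, trace length, horizontal orientation, center cross at the
arc-length midpoint).

Millimeter coordinates use the same raster convention as pixels: origin at
the board's top-left corner, x rightward, y downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._geometry import (
    apply_homography,
    diagonal_extremes,
    dist_to_polyline,
    estimate_projective,
    point_at_arclength,
    polyline_length,
    quad_area,
)
from .errors import CalibrationError, GeometryError

_LENGTH_RTOL = 1e-6


@dataclass
class ZigZagPattern:
    """Geometry of the zig-zag target in millimeters.

    Attributes
    ----------
    apex_points_mm : (m, 2) float array
        Ordered vertices of the center polyline.
    board_width_mm, board_height_mm : float
        Board rectangle; apexes must lie inside it.
    line_width_mm : float
        Thickness of the printed center line (default 1 mm).
    trace_length_mm : float
        Total arc length of the center polyline (default 1000 mm).
    """

    apex_points_mm: np.ndarray
    board_width_mm: float = 420.0
    board_height_mm: float = 297.0
    line_width_mm: float = 1.0
    trace_length_mm: float = 1000.0

    def __post_init__(self):
        self.apex_points_mm = np.asarray(self.apex_points_mm, dtype=float)
        if self.apex_points_mm.ndim != 2 or self.apex_points_mm.shape[1] != 2:
            raise GeometryError("apex_points_mm must be an (m, 2) array")
        if self.apex_points_mm.shape[0] < 2:
            raise GeometryError("a polyline needs at least two apex points")
        if self.line_width_mm <= 0:
            raise GeometryError("line_width_mm must be positive")
        length = polyline_length(self.apex_points_mm)
        if not np.isclose(length, self.trace_length_mm, rtol=_LENGTH_RTOL, atol=0.0):
            raise GeometryError(
                f"polyline length {length:.6f} mm does not match "
                f"trace_length_mm={self.trace_length_mm:.6f}"
            )
        x, y = self.apex_points_mm[:, 0], self.apex_points_mm[:, 1]
        if (x < 0).any() or (x > self.board_width_mm).any() or \
           (y < 0).any() or (y > self.board_height_mm).any():
            raise GeometryError("apex points must lie inside the board rectangle")

    # -- derived geometry ---------------------------------------------------

    @property
    def center_cross_mm(self) -> np.ndarray:
        """Arc-length midpoint of the polyline (the printed center cross)."""
        pts, _ = point_at_arclength(self.apex_points_mm, self.trace_length_mm / 2.0)
        return pts[0]

    @property
    def termini_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """First and last polyline vertex (the two trace end points)."""
        return self.apex_points_mm[0], self.apex_points_mm[-1]

    def corner_points_mm(self) -> np.ndarray:
        """Diagonal-extreme vertices (up-left, up-right, down-left, down-right).

        These are the physical points the image-side corner detector finds:
        among the dark line pixels the extremes of x+y, x-y, y-x, -(x+y).
        For a polyline, each extreme is attained at a vertex.
        """
        return diagonal_extremes(self.apex_points_mm)

    def distance_to_line_mm(self, pts_mm: np.ndarray) -> np.ndarray:
        """Distance from mm-plane points to the center polyline."""
        return dist_to_polyline(pts_mm, self.apex_points_mm)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "apex_points_mm": self.apex_points_mm.tolist(),
            "board_width_mm": self.board_width_mm,
            "board_height_mm": self.board_height_mm,
            "line_width_mm": self.line_width_mm,
            "trace_length_mm": self.trace_length_mm,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ZigZagPattern":
        """Load a pattern from a JSON string or file path."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class CornerSet:
    """Four detected pattern-corner pixels (up-left, up-right, down-left, down-right)."""

    up_left_px: np.ndarray
    up_right_px: np.ndarray
    down_left_px: np.ndarray
    down_right_px: np.ndarray

    def __post_init__(self):
        for name in ("up_left_px", "up_right_px", "down_left_px", "down_right_px"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def as_array(self) -> np.ndarray:
        return np.stack([self.up_left_px, self.up_right_px,
                         self.down_left_px, self.down_right_px])

    @property
    def area_px(self) -> float:
        return quad_area(self.as_array())


@dataclass
class Calibration:
    """Invertible pixel<->mm plane mapping estimated from four corners.

    ``homography`` maps pixel coordinates to board-plane millimeters.
    """

    homography: np.ndarray
    rms_reprojection_px: float = 0.0

    def __post_init__(self):
        self.homography = np.asarray(self.homography, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.homography)) < 1e-12:
            raise CalibrationError("homography is singular")

    def to_mm(self, pts_px: np.ndarray) -> np.ndarray:
        return apply_homography(self.homography, pts_px)

    def to_px(self, pts_mm: np.ndarray) -> np.ndarray:
        return apply_homography(np.linalg.inv(self.homography), pts_mm)

    @property
    def mm_per_px(self) -> float:
        """Approximate isotropic scale at the map's linear part (for diagnostics)."""
        return float(np.sqrt(abs(np.linalg.det(self.homography[:2, :2] / self.homography[2, 2]))))

    def mm_per_px_at(self, pt_px) -> float:
        """Local isotropic mm-per-pixel scale around a pixel position."""
        pt = np.asarray(pt_px, dtype=float)
        base = self.to_mm(pt)[0]
        dx = self.to_mm(pt + [1.0, 0.0])[0] - base
        dy = self.to_mm(pt + [0.0, 1.0])[0] - base
        return float((np.linalg.norm(dx) + np.linalg.norm(dy)) / 2.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_default_pattern(
    n_segments: int = 5,
    board_dims: tuple[float, float] = (420.0, 297.0),
    trace_length_mm: float = 1000.0,
    line_width_mm: float = 1.0,
    margin_mm: float = 10.0,
) -> ZigZagPattern:
    """Construct a symmetric horizontal zig-zag of given total trace length.

    The polyline spans the board horizontally (minus margins) with
    ``n_segments`` equal straight segments whose vertices alternate between
    two horizontal levels.  The level separation (amplitude) is solved from
    the trace-length constraint:

        amplitude = sqrt((L / n)^2 - (span / n)^2)

    with L the trace length and span the horizontal extent.  Vertices start
    on the upper level, so the first terminus is the up-left diagonal
    extreme of the drawn pattern.

    Raises
    ------
    GeometryError
        If ``n_segments < 2`` or no amplitude satisfies the constraint
        inside the board.
    """
    if n_segments < 2:
        raise GeometryError("n_segments must be >= 2 (a single straight segment "
                            "cannot satisfy the zig-zag length constraint)")
    width, height = float(board_dims[0]), float(board_dims[1])
    span = width - 2.0 * margin_mm
    if span <= 0:
        raise GeometryError("margins exceed board width")
    dx = span / n_segments
    seg_len = trace_length_mm / n_segments
    if seg_len <= dx:
        raise GeometryError(
            f"trace length {trace_length_mm} mm is too short for span {span} mm "
            f"with {n_segments} segments (segments would be shorter than their run)"
        )
    amplitude = float(np.sqrt(seg_len**2 - dx**2))
    if amplitude > height - 2.0 * margin_mm:
        raise GeometryError(
            f"required amplitude {amplitude:.2f} mm exceeds usable board height "
            f"{height - 2 * margin_mm:.2f} mm"
        )
    y_top = (height - amplitude) / 2.0
    y_bot = y_top + amplitude
    xs = margin_mm + dx * np.arange(n_segments + 1)
    ys = np.where(np.arange(n_segments + 1) % 2 == 0, y_top, y_bot)
    return ZigZagPattern(
        apex_points_mm=np.column_stack([xs, ys]),
        board_width_mm=width,
        board_height_mm=height,
        line_width_mm=line_width_mm,
        trace_length_mm=trace_length_mm,
    )


def calibrate(corners: CornerSet, pattern: ZigZagPattern) -> Calibration:
    """Estimate the pixel->mm homography from the four detected corners.

    The four detected pixel extremes are matched to the mm positions of the
    pattern vertices that are extreme under the same diagonal functionals
    (up-left = argmin(x+y), etc.), and an exact-fit 4-point plane homography
    is estimated.  A full projective map is used rather than a similarity
    because the camera sits behind and lateral to the shoulder, so the board
    is seen under perspective.
    """
    src = corners.as_array()
    if corners.area_px < 1e-9:
        raise CalibrationError("corner quadrilateral is degenerate (zero area)")
    dst = pattern.corner_points_mm()
    if quad_area(dst) < 1e-9:
        raise CalibrationError("pattern diagonal extremes are degenerate")
    params = estimate_projective(src, dst)
    if params is None:
        raise CalibrationError("homography estimation failed (collinear corners?)")
    cal = Calibration(homography=params, rms_reprojection_px=0.0)
    back = cal.to_px(dst)
    cal.rms_reprojection_px = float(np.sqrt(np.mean(np.sum((back - src) ** 2, axis=1))))
    return cal


def line_mask(
    pattern: ZigZagPattern,
    calibration: Calibration,
    image_dims: tuple[int, int],
    tolerance_mm: float = 0.0,
) -> np.ndarray:
    """Binary mask of pixels whose mm-plane position lies on the target line.

    A pixel is on the line when its center, mapped to the board plane, is
    within ``line_width_mm / 2 + tolerance_mm`` of the center polyline.

    Parameters
    ----------
    image_dims : (width, height) in pixels.

    Returns
    -------
    bool array of shape (height, width).
    """
    width, height = image_dims
    xx, yy = np.meshgrid(np.arange(width, dtype=float),
                         np.arange(height, dtype=float))
    pts_px = np.column_stack([xx.ravel(), yy.ravel()])
    pts_mm = calibration.to_mm(pts_px)
    d = pattern.distance_to_line_mm(pts_mm)
    limit = pattern.line_width_mm / 2.0 + tolerance_mm
    return (d <= limit).reshape(height, width)
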