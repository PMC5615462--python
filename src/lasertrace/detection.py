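"""Per-frame image detection: pattern corners and the laser dot.

Corner detection follows the binarization route: grayscale conversion, a
dark threshold restricted to the (green) board region, then the four most
distant on-pixels along the image diagonals.  Dot detection binarizes the
color frame by red dominance, clears artifacts by morphological opening and
an area band-pass, and keeps the largest surviving connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._geometry import diagonal_extremes, quad_area
from .errors import NoPatternFound
from .pattern import Calibration, CornerSet

# Rec. 601 luma weights: the de-facto grayscale conversion for video frames.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DotObservation:
    """Result of laser-dot detection in one frame.

    When ``detected`` is False all measurement fields are ``None`` (never
    zero-filled): an occluded or absent dot is a valid observation.
    ``pixel_coords`` holds the component's (rows, cols) pixel indices and is
    used for the on-line overlap test; it is not serialized.
    """

    frame_index: int
    time_s: float
    detected: bool
    centroid_px: np.ndarray | None = None
    centroid_mm: np.ndarray | None = None
    area_px: int | None = None
    on_line: bool | None = None
    pixel_coords: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def _as_channels(frame: np.ndarray):
    img = np.asarray(frame)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) color frame")
    return img[..., 0].astype(np.int16), img[..., 1].astype(np.int16), img[..., 2].astype(np.int16)


def _red_dominance_mask(frame, t_abs: int, t_margin: int, near_max: int) -> np.ndarray:
    """Binarize a frame into candidate laser pixels.

    A pixel is laser-like when it is strongly red (R >= t_abs and the red
    channel dominates green/blue by t_margin) or near-saturated (R >=
    near_max): real laser dots bleach to a white-pink core that fails the
    margin test but is still part of the dot.
    """
    r, g, b = _as_channels(frame)
    dominant = (r >= t_abs) & ((r - np.maximum(g, b)) >= t_margin)
    saturated = r >= near_max
    return dominant | saturated


def board_region_mask(frame: np.ndarray, green_margin: int = 10) -> np.ndarray:
    """Largest green-dominant connected region of the frame, holes filled.

    The target board is green; this restricts dark-pixel thresholding to the
    board so that shadows or dark objects elsewhere in the scene cannot
    masquerade as line pixels.
    """
    r, g, b = _as_channels(frame)
    greenish = (g >= r + green_margin) & (g >= b + green_margin)
    if not greenish.any():
        return np.zeros(greenish.shape, dtype=bool)
    labels, n = ndimage.label(greenish)
    if n == 0:
        return np.zeros(greenish.shape, dtype=bool)
    largest = np.argmax(ndimage.sum_labels(greenish, labels, index=np.arange(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labels == largest)


def detect_corners(
    image: np.ndarray,
    dark_threshold: float | None = None,
    green_margin: int = 10,
    red_exclusion: dict | None = None,
) -> CornerSet:
    """Detect the four pattern corners in a color image.

    The image is converted to grayscale and thresholded to isolate the black
    line inside the green board region; among the on-pixels the four most
    distant along the diagonals are returned: up-left = argmin(x+y),
    up-right = argmax(x-y), down-left = argmax(y-x), down-right =
    argmax(x+y).  Red-dominant pixels (the laser dot) are excluded before
    thresholding so the dot's position cannot perturb the corners.

    Parameters
    ----------
    dark_threshold : float, optional
        Grayscale cutoff (0-255) below which a board pixel counts as line.
        Default: Otsu's threshold computed over the board region.

    Raises
    ------
    NoPatternFound
        If there are no dark on-pixels or the four extremes form a
        degenerate (near-zero-area) quadrilateral.
    """
    img = np.asarray(image)
    gray = img[..., :3].astype(float) @ _LUMA
    board = board_region_mask(img, green_margin=green_margin)
    if not board.any():
        raise NoPatternFound("no green board region found in image")
    excl = red_exclusion or {}
    red = _red_dominance_mask(img, excl.get("t_abs", 150), excl.get("t_margin", 60),
                              excl.get("near_max", 245))
    candidates = board & ~red
    if dark_threshold is None:
        vals = gray[candidates]
        if vals.size == 0:
            raise NoPatternFound("board region is empty after red exclusion")
        dark_threshold = threshold_otsu(vals)
    on = candidates & (gray < dark_threshold)
    rows, cols = np.nonzero(on)
    if rows.size == 0:
        raise NoPatternFound("no dark on-pixels inside the board region")
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    corners = diagonal_extremes(pts)
    if quad_area(corners) < 1.0:
        raise NoPatternFound("corner quadrilateral is degenerate "
                             "(dark pixels nearly collinear or a single blob)")
    return CornerSet(*corners)


def detect_dot(
    frame: np.ndarray,
    exclusion: np.ndarray | None = None,
    *,
    frame_index: int = 0,
    time_s: float = 0.0,
    t_abs: int = 150,
    t_margin: int = 60,
    near_max: int = 245,
    min_dot_area: int = 10,
    max_dot_area: int = 5000,
    calibration: Calibration | None = None,
) -> DotObservation:
    """Detect the laser dot in one color frame.

    Pipeline: red-dominance binarization -> optional exclusion mask ->
    3x3 morphological opening -> connected components -> area band-pass
    [min_dot_area, max_dot_area] -> keep the largest survivor.  Absence of a
    dot is a valid observation (``detected=False``), not an error.

    Parameters
    ----------
    exclusion : bool array, optional
        Pixels set True are removed from consideration (e.g. regions outside
        the board).
    calibration : Calibration, optional
        When given, the centroid is also expressed in board millimeters.
    """
    red = _red_dominance_mask(frame, t_abs, t_margin, near_max)
    if exclusion is not None:
        red &= ~exclusion
    if not red.any():
        return DotObservation(frame_index, time_s, detected=False)

    # crop to the candidate bounding box: opening/labelling on a small patch
    rows, cols = np.nonzero(red)
    r0, r1 = max(rows.min() - 2, 0), min(rows.max() + 3, red.shape[0])
    c0, c1 = max(cols.min() - 2, 0), min(cols.max() + 3, red.shape[1])
    patch = red[r0:r1, c0:c1]
    # opening by reconstruction: the opening clears speckle artifacts, but a
    # surviving component keeps its exact pre-opening pixel set (boundary
    # pixels matter for the on-line overlap test)
    opened = ndimage.binary_opening(patch, structure=np.ones((3, 3), dtype=bool))
    labels, n = ndimage.label(patch)
    if n == 0 or not opened.any():
        return DotObservation(frame_index, time_s, detected=False)
    survivors = np.unique(labels[opened])
    survivors = survivors[survivors > 0]
    sizes = ndimage.sum_labels(patch, labels, index=survivors)
    ok = (sizes >= min_dot_area) & (sizes <= max_dot_area)
    if not ok.any():
        return DotObservation(frame_index, time_s, detected=False)
    best = survivors[ok][np.argmax(sizes[ok])]
    pr, pc = np.nonzero(labels == best)
    rr, cc = pr + r0, pc + c0
    centroid_px = np.array([cc.mean(), rr.mean()])
    centroid_mm = calibration.to_mm(centroid_px)[0] if calibration is not None else None
    return DotObservation(
        frame_index, time_s, detected=True,
        centroid_px=centroid_px, centroid_mm=centroid_mm,
        area_px=int(rr.size), pixel_coords=(rr, cc),
    )


def classify_on_line(dot: DotObservation, mask: np.ndarray, min_overlap_px: int = 1) -> bool | None:
    """Whether the dot's pixel set touches the target-line mask.

    True iff at least ``min_overlap_px`` of the dot's component pixels fall
    on the line mask.  Returns ``None`` for an undetected dot (absent flag).
    """
    if not dot.detected or dot.pixel_coords is None:
        return None
    rr, cc = dot.pixel_coords
    return int(mask[rr, cc].sum()) >= min_overlap_px
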