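"""Trial scoring: segmentation, Acuity, Speed, direction labels, aggregation.

A trial is a frame stream of one tracing movement.  The dot is detected per
frame, the trial window is found from the dot's distance to the terminal
corners of the zig-zag, and two outcomes are computed over the window:

* **Acuity** — percentage of trial time the dot touches the target line.
* **Speed** — average movement speed in mm/s, either as centroid-trajectory
  arc length / duration (default) or nominal trace length / duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .detection import DotObservation, classify_on_line, detect_corners, detect_dot
from .errors import LaserTraceError, TrialNotSegmentable
from .pattern import Calibration, ZigZagPattern, calibrate, line_mask

logger = logging.getLogger(__name__)

#: (hand, draw_direction) -> anatomical movement direction.  A clockwise
#: (left-to-right) trace is a palmar movement for the left hand and a dorsal
#: movement for the right hand; anticlockwise is the reverse.
DIRECTION_MAP = {
    ("left", "clockwise"): "palmar",
    ("right", "clockwise"): "dorsal",
    ("left", "anticlockwise"): "dorsal",
    ("right", "anticlockwise"): "palmar",
}


@dataclass
class TrialResult:
    start_frame: int
    end_frame: int
    duration_s: float
    acuity_pct: float
    speed_mm_s: float
    speed_nominal_mm_s: float
    path_length_mm: float
    n_frames_total: int
    n_frames_detected: int
    n_frames_on_line: int

    def __post_init__(self):
        if not (0.0 <= self.acuity_pct <= 100.0):
            raise LaserTraceError(f"acuity out of range: {self.acuity_pct}")
        if self.start_frame >= self.end_frame:
            raise LaserTraceError("start_frame must precede end_frame")
        if not (self.n_frames_on_line <= self.n_frames_detected <= self.n_frames_total):
            raise LaserTraceError("frame counters are inconsistent")


@dataclass
class SessionRecord:
    """One scored trial with its session metadata."""

    participant_id: str
    hand: str
    draw_direction: str
    trial_number: int
    result: TrialResult
    anatomical_direction: str = field(init=False)

    def __post_init__(self):
        self.anatomical_direction = label_direction(self.hand, self.draw_direction)


def label_direction(hand: str, draw_direction: str) -> str:
    """Anatomical wrist-movement label from hand and drawing direction."""
    try:
        return DIRECTION_MAP[(hand, draw_direction)]
    except KeyError:
        raise LaserTraceError(
            f"invalid (hand, draw_direction): {(hand, draw_direction)!r}"
        ) from None


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(flags: np.ndarray):
    """Maximal runs of True as (first_idx, last_idx) pairs."""
    out = []
    idx = np.nonzero(flags)[0]
    if idx.size == 0:
        return out
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def segment_trial(
    observations: list[DotObservation],
    start_corner_mm: np.ndarray,
    end_corner_mm: np.ndarray,
    radius_mm: float = 10.0,
    dwell_frames: int = 5,
) -> tuple[int, int]:
    """Locate the trial window from dot-to-corner distances.

    The start frame is the last frame of the first run of at least
    ``dwell_frames`` consecutive frames with the dot within ``radius_mm`` of
    the start corner (i.e. the moment of sustained departure); the end frame
    is the first frame of the first subsequent such run at the end corner.
    Undetected frames break a run.

    Returns positional indices into ``observations``.

    Raises
    ------
    TrialNotSegmentable
        If the dot never dwells long enough at the start or end corner.
    """
    n = len(observations)
    d_start = np.full(n, np.inf)
    d_end = np.full(n, np.inf)
    for i, obs in enumerate(observations):
        if obs.detected and obs.centroid_mm is not None:
            d_start[i] = np.linalg.norm(obs.centroid_mm - np.asarray(start_corner_mm))
            d_end[i] = np.linalg.norm(obs.centroid_mm - np.asarray(end_corner_mm))

    start_runs = [r for r in _runs(d_start <= radius_mm) if r[1] - r[0] + 1 >= dwell_frames]
    if not start_runs:
        raise TrialNotSegmentable("start")
    start = start_runs[0][1]

    end_runs = [r for r in _runs(d_end <= radius_mm)
                if r[0] > start and r[1] - r[0] + 1 >= dwell_frames]
    if not end_runs:
        raise TrialNotSegmentable("end")
    end = end_runs[0][0]
    return start, end


# ---------------------------------------------------------------------------
# outcome variables
# ---------------------------------------------------------------------------

def compute_acuity(
    observations: list[DotObservation],
    start_frame: int,
    end_frame: int,
    denominator: str = "all",
) -> float:
    """Percentage of the trial window with the dot on the target line.

    ``denominator="all"`` counts every frame of the window (undetected
    frames score off-line), matching a definition over trial *time*;
    ``"detected"`` restricts to frames with a detection.
    """
    window = observations[start_frame:end_frame + 1]
    if not window:
        raise LaserTraceError("empty trial window")
    on = sum(1 for o in window if o.on_line)
    if denominator == "all":
        denom = len(window)
    elif denominator == "detected":
        denom = sum(1 for o in window if o.detected)
        if denom == 0:
            raise LaserTraceError("no detected frames in trial window")
    else:
        raise LaserTraceError(f"unknown denominator mode {denominator!r}")
    return 100.0 * on / denom


def _smooth(track: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(track) < 2:
        return track
    pad = window // 2
    padded = np.pad(track, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.column_stack([
        np.convolve(padded[:, j], kernel, mode="valid") for j in range(track.shape[1])
    ])


def compute_speed(
    observations: list[DotObservation],
    start_frame: int,
    end_frame: int,
    mode: str = "arc_length",
    trace_length_mm: float | None = None,
    smooth_window: int = 1,
) -> tuple[float, float]:
    """Average movement speed over the trial window, in mm/s.

    ``arc_length`` mode sums consecutive mm displacements of the detected
    centroid (gaps from undetected frames are bridged by straight segments)
    and divides by the window duration.  ``nominal`` mode divides the
    pattern's trace length by the duration.

    Returns ``(speed_mm_s, path_length_mm)``; for nominal mode the path
    length is the trace length.
    """
    window = observations[start_frame:end_frame + 1]
    duration = window[-1].time_s - window[0].time_s
    if duration <= 0:
        raise LaserTraceError("trial window has non-positive duration")
    if mode == "nominal":
        if trace_length_mm is None:
            raise LaserTraceError("nominal mode requires trace_length_mm")
        return trace_length_mm / duration, float(trace_length_mm)
    if mode != "arc_length":
        raise LaserTraceError(f"unknown speed mode {mode!r}")
    track = np.array([o.centroid_mm for o in window
                      if o.detected and o.centroid_mm is not None])
    if len(track) < 2:
        raise LaserTraceError("need >= 2 detected frames to compute arc-length speed")
    track = _smooth(track, smooth_window)
    path = float(np.linalg.norm(np.diff(track, axis=0), axis=1).sum())
    return path / duration, path


# ---------------------------------------------------------------------------
# full-trial orchestration
# ---------------------------------------------------------------------------

@dataclass
class TrialScore:
    """Scored trial plus the intermediate artifacts useful for debugging."""

    result: TrialResult
    observations: list[DotObservation]
    calibration: Calibration
    mask: np.ndarray


def score_trial(
    source,
    pattern: ZigZagPattern,
    config: RunConfig | None = None,
    draw_direction: str = "clockwise",
) -> TrialScore:
    """Run the complete per-trial pipeline on a frame source.

    ``source`` is any :class:`~lasertrace.io.FrameSource`: it must expose
    ``fps``, ``n_frames``, ``get(i)`` and iteration over frames.  Corners
    are detected once (on the configured reference frame), the pixel->mm
    calibration and line mask are built, every frame is scanned for the dot,
    and the trial window and outcomes are computed.
    """
    config = config or RunConfig()
    if config.corner_frame == "middle":
        ref_idx = source.n_frames // 2
    elif config.corner_frame == "first":
        ref_idx = 0
    else:
        ref_idx = int(config.corner_frame)
    ref = source.get(ref_idx)
    corners = detect_corners(
        ref, dark_threshold=config.dark_threshold,
        red_exclusion={"t_abs": config.t_abs, "t_margin": config.t_margin,
                       "near_max": config.near_max},
    )
    cal = calibrate(corners, pattern)
    h, w = np.asarray(ref).shape[:2]
    tol = config.on_line_tolerance_mm
    if tol is None:
        # quarter pixel side: mean quantization margin of a center-sampled
        # region boundary; restores the continuous "touching" criterion
        # without bias
        tol = 0.25 * cal.mm_per_px_at(np.array([w / 2.0, h / 2.0]))
    mask = line_mask(pattern, cal, (w, h), tolerance_mm=tol)

    observations: list[DotObservation] = []
    for i, frame in enumerate(source):
        obs = detect_dot(
            frame, frame_index=i, time_s=i / source.fps,
            t_abs=config.t_abs, t_margin=config.t_margin, near_max=config.near_max,
            min_dot_area=config.min_dot_area, max_dot_area=config.max_dot_area,
            calibration=cal,
        )
        if obs.detected:
            obs.on_line = classify_on_line(obs, mask, config.min_overlap_px)
        else:
            logger.debug("frame %d: no dot detected", i)
        observations.append(obs)

    if config.interpolate_gaps > 0:
        _fill_short_gaps(observations, config.interpolate_gaps)

    a, b = pattern.termini_mm
    left, right = (a, b) if a[0] <= b[0] else (b, a)
    start_corner, end_corner = (left, right) if draw_direction == "clockwise" else (right, left)

    start, end = segment_trial(observations, start_corner, end_corner,
                               radius_mm=config.radius_mm,
                               dwell_frames=config.dwell_frames)
    acuity = compute_acuity(observations, start, end,
                            denominator=config.acuity_denominator)
    speed_arc, path = compute_speed(observations, start, end, mode="arc_length",
                                    smooth_window=config.smooth_window)
    duration = observations[end].time_s - observations[start].time_s
    speed_nominal = pattern.trace_length_mm / duration
    window = observations[start:end + 1]
    result = TrialResult(
        start_frame=start, end_frame=end, duration_s=duration,
        acuity_pct=acuity,
        speed_mm_s=speed_arc if config.speed_mode == "arc_length" else speed_nominal,
        speed_nominal_mm_s=speed_nominal,
        path_length_mm=path,
        n_frames_total=len(window),
        n_frames_detected=sum(1 for o in window if o.detected),
        n_frames_on_line=sum(1 for o in window if o.on_line),
    )
    logger.info("trial scored: frames %d-%d, acuity %.1f%%, speed %.1f mm/s",
                start, end, acuity, result.speed_mm_s)
    return TrialScore(result=result, observations=observations,
                      calibration=cal, mask=mask)


def _fill_short_gaps(observations: list[DotObservation], max_gap: int) -> None:
    """Linearly interpolate centroid_mm across short undetected gaps.

    Only the mm centroid is filled (for trajectory continuity); the
    ``detected`` flag stays False and the fill is logged.
    """
    det = [i for i, o in enumerate(observations) if o.detected]
    for a, b in zip(det[:-1], det[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            pa, pb = observations[a].centroid_mm, observations[b].centroid_mm
            for j in range(1, gap + 1):
                t = j / (gap + 1)
                observations[a + j].centroid_mm = (1 - t) * pa + t * pb
            logger.debug("interpolated %d-frame gap at frames %d-%d", gap, a + 1, b - 1)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def records_to_frame(records: list[SessionRecord]) -> pd.DataFrame:
    """Flatten session records into the interchange trial table."""
    rows = []
    for r in records:
        res = r.result
        rows.append({
            "participant": r.participant_id,
            "hand": r.hand,
            "draw_direction": r.draw_direction,
            "anatomical_direction": r.anatomical_direction,
            "trial": r.trial_number,
            "start_frame": res.start_frame,
            "end_frame": res.end_frame,
            "duration_s": res.duration_s,
            "acuity_pct": res.acuity_pct,
            "speed_arc_mm_s": res.path_length_mm / res.duration_s,
            "speed_nominal_mm_s": res.speed_nominal_mm_s,
            "n_frames_total": res.n_frames_total,
            "n_frames_detected": res.n_frames_detected,
            "n_frames_on_line": res.n_frames_on_line,
            "path_length_mm": res.path_length_mm,
        })
    return pd.DataFrame(rows)


def aggregate_condition(records) -> pd.DataFrame:
    """Mean Acuity and Speed per (participant, hand, anatomical direction).

    Accepts a list of :class:`SessionRecord` or a trial table DataFrame.
    Conditions with available trials are averaged over whatever trials exist
    (1-3); the trial count is recorded so partially missing conditions are
    visible.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        logger.warning("no trials to aggregate")
        return pd.DataFrame(columns=["participant", "hand", "anatomical_direction",
                                     "n_trials", "acuity_pct", "speed_mm_s"])
    speed_col = "speed_arc_mm_s" if "speed_arc_mm_s" in df else "speed_mm_s"
    grouped = (
        df.groupby(["participant", "hand", "anatomical_direction"], sort=True)
        .agg(n_trials=("trial", "count"),
             acuity_pct=("acuity_pct", "mean"),
             speed_mm_s=(speed_col, "mean"))
        .reset_index()
    )
    return grouped
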