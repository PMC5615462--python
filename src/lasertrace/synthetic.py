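"""Seeded synthetic trial scenes with analytic ground truth.

The generator emulates the physical test setup: a green A3 board on a wall
with a 1 mm black zig-zag center line (1 m trace), filmed at 1280x720 @ 30
fps under mild camera perspective, while a red laser dot with a saturated
white-pink core advances along the line with a jittered speed profile and an
AR(1)-correlated lateral error.  Every frame and the full ground truth
(true dot center, on-line flag, trial window, arc length) are reproducible
from the seed, which makes each pipeline stage testable without real video.

The lateral error is AR(1) rather than white noise because hand tremor and
corrective movements are temporally correlated; this stresses the run-length
behavior the on/off-line classifier sees on real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geometry import (apply_homography, dist_to_polyline,
                        estimate_projective, point_at_arclength)
from .errors import GeometryError, LaserTraceError
from .io import FrameSource
from .pattern import ZigZagPattern, build_default_pattern
from .pipeline import _runs, label_direction


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

def make_camera(
    image_dims: tuple[int, int],
    pattern: ZigZagPattern,
    perspective: float = 0.04,
    rotation_deg: float = 1.5,
    jitter_px: float = 0.0,
    margin_px: float = 40.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """mm -> pixel homography for a camera viewing the board obliquely.

    The board rectangle is mapped to a centered pixel quadrilateral whose
    top edge is shrunk by ``perspective`` (keystone from the oblique camera
    position), rotated by ``rotation_deg`` and optionally jittered per
    corner by up to ``jitter_px`` (uniform, from ``rng``).
    """
    w_img, h_img = image_dims
    bw, bh = pattern.board_width_mm, pattern.board_height_mm
    scale = min((w_img - 2 * margin_px) / bw, (h_img - 2 * margin_px) / bh)
    if scale <= 0:
        raise GeometryError("image too small for the board")
    pw, ph = bw * scale, bh * scale
    x0, y0 = (w_img - pw) / 2.0, (h_img - ph) / 2.0
    quad = np.array([
        [x0 + perspective * pw, y0],
        [x0 + pw - perspective * pw, y0],
        [x0 + pw, y0 + ph],
        [x0, y0 + ph],
    ])
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        center = quad.mean(axis=0)
        quad = (quad - center) @ rot.T + center
    if jitter_px:
        rng = rng or np.random.default_rng(0)
        quad = quad + rng.uniform(-jitter_px, jitter_px, size=quad.shape)
    src = np.array([[0.0, 0.0], [bw, 0.0], [bw, bh], [0.0, bh]])
    params = estimate_projective(src, quad)
    if params is None:
        raise GeometryError("camera homography estimation failed")
    return params


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one synthetic trial scene.

    Defaults reproduce the clinical recording conditions: 1280x720 @ 30 fps,
    A3 board with a 1 mm line and 1 m trace, red laser dot about 2.5 mm in
    radius, self-paced tracing around 55 mm/s, and a mild oblique camera.
    """

    pattern: ZigZagPattern = field(default_factory=build_default_pattern)
    image_dims: tuple[int, int] = (1280, 720)
    fps: float = 30.0
    camera: np.ndarray | None = None           # mm->px homography; None = default
    dot_radius_mm: float = 2.5
    dot_color: tuple[int, int, int] = (230, 40, 40)
    core_color: tuple[int, int, int] = (255, 215, 215)
    core_fraction: float = 0.5                 # radius fraction of saturated core
    speed_mean_mm_s: float = 55.0
    speed_jitter_sd: float = 5.0               # per-frame speed SD, mm/s
    lateral_sd_mm: float = 2.0                 # stationary SD of lateral error
    lateral_ar1: float = 0.9                   # AR(1) correlation at 30 fps
    dwell_s: float = 1.0                       # hold at each terminus
    pixel_noise_sd: float = 3.0                # additive Gaussian, intensity units
    draw_direction: str = "clockwise"          # clockwise = left-to-right
    board_color: tuple[int, int, int] = (60, 150, 70)
    line_color: tuple[int, int, int] = (25, 25, 25)
    background_color: tuple[int, int, int] = (205, 205, 205)
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise LaserTraceError("fps must be positive")
        if self.dot_radius_mm <= 0:
            raise LaserTraceError("dot_radius_mm must be positive")
        if not (0.0 <= self.lateral_ar1 < 1.0):
            raise LaserTraceError("lateral_ar1 must be in [0, 1)")
        if self.draw_direction not in ("clockwise", "anticlockwise"):
            raise LaserTraceError(f"draw_direction: {self.draw_direction!r}")
        if self.camera is None:
            self.camera = make_camera(self.image_dims, self.pattern)
        else:
            self.camera = np.asarray(self.camera, dtype=float).reshape(3, 3)


@dataclass
class GroundTruth:
    """Analytic per-frame truth for one synthetic trial."""

    center_mm: np.ndarray          # (n, 2)
    center_px: np.ndarray          # (n, 2)
    lateral_error_mm: np.ndarray   # (n,) distance from dot center to polyline
    on_line: np.ndarray            # (n,) bool: lateral <= dot radius + half width
    start_frame: int
    end_frame: int
    arc_length_mm: float           # sum of consecutive displacements in the window
    on_line_fraction: float        # over the trial window
    arc_position_mm: np.ndarray    # (n,) arc-length coordinate along the trace

    @property
    def n_frames(self) -> int:
        return len(self.on_line)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _simulate_path(config: SimConfig):
    """Arc-length schedule and lateral-error series for one trial."""
    rng = np.random.default_rng([config.seed, 1])
    fps, L = config.fps, config.pattern.trace_length_mm
    n_dwell = int(round(config.dwell_s * fps))
    s_list = [0.0] * max(n_dwell, 1)
    s = 0.0
    guard = int(1e7)
    while s < L - 1e-9:
        step = max(rng.normal(config.speed_mean_mm_s, config.speed_jitter_sd), 0.0) / fps
        s = min(s + step, L)
        s_list.append(s)
        guard -= 1
        if guard <= 0:
            raise LaserTraceError("speed profile never reaches the end of the trace")
    s_list.extend([L] * n_dwell)
    s_arr = np.array(s_list)
    if config.draw_direction == "anticlockwise":
        s_arr = L - s_arr
    n = len(s_arr)
    sigma, rho = config.lateral_sd_mm, config.lateral_ar1
    e = np.zeros(n)
    if sigma > 0:
        innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho**2), size=n)
        e[0] = rng.normal(0.0, sigma)
        for t in range(1, n):
            e[t] = rho * e[t - 1] + innov[t]
    return s_arr, e


def _truth_segment(d_start, d_end, radius_mm, dwell_frames):
    """Trial window on the true path, same rule as the pipeline segmenter."""
    start_runs = [r for r in _runs(d_start <= radius_mm)
                  if r[1] - r[0] + 1 >= dwell_frames]
    if not start_runs:
        raise LaserTraceError("true path never dwells at the start terminus")
    start = start_runs[0][1]
    end_runs = [r for r in _runs(d_end <= radius_mm)
                if r[0] > start and r[1] - r[0] + 1 >= dwell_frames]
    if not end_runs:
        raise LaserTraceError("true path never dwells at the end terminus")
    return start, end_runs[0][0]


def generate_trial(
    config: SimConfig,
    radius_mm: float = 10.0,
    dwell_frames: int = 5,
) -> tuple["SyntheticTrialSource", GroundTruth]:
    """Render one synthetic trial and its analytic ground truth.

    ``radius_mm``/``dwell_frames`` define the trial window on the *true*
    path with the same rule the pipeline segmenter uses, so recovered start
    and end frames are directly comparable.
    """
    s_arr, e = _simulate_path(config)
    pts, tangents = point_at_arclength(config.pattern.apex_points_mm, s_arr)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    center_mm = pts + normals * e[:, None]
    center_px = apply_homography(config.camera, center_mm)
    lateral = dist_to_polyline(center_mm, config.pattern.apex_points_mm)
    threshold = config.dot_radius_mm + config.pattern.line_width_mm / 2.0
    on_line = lateral <= threshold

    a, b = config.pattern.termini_mm
    left, right = (a, b) if a[0] <= b[0] else (b, a)
    start_c, end_c = (left, right) if config.draw_direction == "clockwise" else (right, left)
    d_start = np.linalg.norm(center_mm - start_c, axis=1)
    d_end = np.linalg.norm(center_mm - end_c, axis=1)
    start, end = _truth_segment(d_start, d_end, radius_mm, dwell_frames)

    window = slice(start, end + 1)
    arc = float(np.linalg.norm(np.diff(center_mm[window], axis=0), axis=1).sum())
    truth = GroundTruth(
        center_mm=center_mm, center_px=center_px,
        lateral_error_mm=lateral, on_line=on_line,
        start_frame=start, end_frame=end,
        arc_length_mm=arc,
        on_line_fraction=float(on_line[window].mean()),
        arc_position_mm=s_arr,
    )
    return SyntheticTrialSource(config, truth), truth


class SyntheticTrialSource(FrameSource):
    """Frame source rendering a synthetic trial on demand.

    Frames are rendered per index from the precomputed true path, so the
    source is random-access and bit-identical across iterations: frame
    ``i``'s pixel noise comes from a generator seeded by ``(seed, i)``.
    """

    def __init__(self, config: SimConfig, truth: GroundTruth):
        self.config = config
        self.truth = truth
        self.fps = config.fps
        self.n_frames = truth.n_frames
        self._bg = None
        self._inv_camera = np.linalg.inv(config.camera)

    def _background(self) -> np.ndarray:
        if self._bg is not None:
            return self._bg
        cfg = self.config
        w, h = cfg.image_dims
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        mm = apply_homography(self._inv_camera, np.column_stack([xx.ravel(), yy.ravel()]))
        img = np.empty((h * w, 3), dtype=np.uint8)
        img[:] = cfg.background_color
        on_board = ((mm[:, 0] >= 0) & (mm[:, 0] <= cfg.pattern.board_width_mm) &
                    (mm[:, 1] >= 0) & (mm[:, 1] <= cfg.pattern.board_height_mm))
        img[on_board] = cfg.board_color
        idx = np.nonzero(on_board)[0]
        d = dist_to_polyline(mm[idx], cfg.pattern.apex_points_mm)
        img[idx[d <= cfg.pattern.line_width_mm / 2.0]] = cfg.line_color
        self._bg = img.reshape(h, w, 3)
        return self._bg

    def _draw_dot(self, img: np.ndarray, i: int) -> None:
        cfg = self.config
        h, w = img.shape[:2]
        c_mm = self.truth.center_mm[i]
        c_px = self.truth.center_px[i]
        if not np.isfinite(c_mm).all():
            return
        # conservative pixel radius from the local scale of the camera map
        probe = apply_homography(cfg.camera, c_mm + np.array(
            [[cfg.dot_radius_mm, 0], [-cfg.dot_radius_mm, 0],
             [0, cfg.dot_radius_mm], [0, -cfg.dot_radius_mm]]))
        r_px = int(np.ceil(np.abs(probe - c_px).max())) + 2
        x0, x1 = max(int(c_px[0]) - r_px, 0), min(int(c_px[0]) + r_px + 1, w)
        y0, y1 = max(int(c_px[1]) - r_px, 0), min(int(c_px[1]) + r_px + 1, h)
        if x0 >= x1 or y0 >= y1:
            return
        xx, yy = np.meshgrid(np.arange(x0, x1, dtype=float),
                             np.arange(y0, y1, dtype=float))
        mm = apply_homography(self._inv_camera, np.column_stack([xx.ravel(), yy.ravel()]))
        d = np.linalg.norm(mm - c_mm, axis=1).reshape(yy.shape)
        patch = img[y0:y1, x0:x1]
        patch[d <= cfg.dot_radius_mm] = cfg.dot_color
        patch[d <= cfg.dot_radius_mm * cfg.core_fraction] = cfg.core_color

    def get(self, i: int) -> np.ndarray:
        if not (0 <= i < self.n_frames):
            raise IndexError(i)
        img = self._background().copy()
        self._draw_dot(img, i)
        if self.config.pixel_noise_sd > 0:
            rng = np.random.default_rng([self.config.seed, 1000, i])
            noise = rng.standard_normal(img.shape, dtype=np.float32) * self.config.pixel_noise_sd
            img = np.clip(img.astype(np.float32) + noise, 0, 255).astype(np.uint8)
        return img


def render_scene(config: SimConfig, dot_center_mm=None) -> np.ndarray:
    """Render a single frame: the board scene with an optional dot.

    Convenience for unit fixtures; uses the config's camera, colors, noise
    and seed.  ``dot_center_mm=None`` renders the dot-free scene.
    """
    c = np.full(2, np.nan) if dot_center_mm is None else \
        np.asarray(dot_center_mm, dtype=float)
    c_px = (np.full((1, 2), np.nan) if dot_center_mm is None
            else apply_homography(config.camera, c[None, :]))
    truth = GroundTruth(
        center_mm=c[None, :], center_px=c_px,
        lateral_error_mm=np.zeros(1), on_line=np.zeros(1, dtype=bool),
        start_frame=0, end_frame=0, arc_length_mm=0.0,
        on_line_fraction=0.0, arc_position_mm=np.zeros(1),
    )
    return SyntheticTrialSource(config, truth).get(0)


# ---------------------------------------------------------------------------
# cohort generation (parametric, no rendering)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffects:
    """Population effects of the simulated cohort.

    Defaults mirror a study-like population: a ~5 acuity-point advantage of
    the dominant hand, a ~6-point deficit with a painful (right) hand, and a
    ~1-point per-trial learning improvement.
    """

    dominant_gain: float = 5.0
    pain_deficit: float = 6.0
    learning_per_trial: float = 1.0


def generate_cohort(
    n_subjects: int = 50,
    effects: CohortEffects | None = None,
    seed: int = 0,
    acuity_mean: float = 70.0,
    acuity_subject_sd: float = 10.0,
    acuity_trial_sd: float = 5.5,
    speed_mean: float = 55.0,
    speed_subject_sd: float = 20.0,
    speed_trial_sd: float = 5.0,
    speed_acuity_rho: float = -0.65,
    pain_prevalence: float = 0.2,
    right_handed_fraction: float = 0.9,
    n_trials: int = 3,
    missing_rate: float = 0.0,
    fps: float = 30.0,
    trace_length_mm: float = 1000.0,
):
    """Draw a study-shaped cohort of scored trials without rendering video.

    Each subject performs both hands x both draw directions x ``n_trials``
    trials (12 by default).  Subject-level acuity and speed are a correlated
    bivariate normal (the speed-accuracy trade-off); trial scores add the
    dominant-hand gain, an optional pain deficit on the affected (right)
    hand, a per-trial learning shift and i.i.d. trial noise.

    Returns
    -------
    (trials, subjects) : (DataFrame, DataFrame)
        ``trials`` uses the same schema as the video pipeline's trial table;
        ``subjects`` holds the generating per-subject parameters.
    """
    if n_subjects < 1:
        raise LaserTraceError("n_subjects must be >= 1")
    eff = effects or CohortEffects()
    rng = np.random.default_rng([seed, 2])
    cov = np.array([
        [acuity_subject_sd**2, speed_acuity_rho * acuity_subject_sd * speed_subject_sd],
        [speed_acuity_rho * acuity_subject_sd * speed_subject_sd, speed_subject_sd**2],
    ])
    base = rng.multivariate_normal([acuity_mean, speed_mean], cov, size=n_subjects)
    dominant = np.where(rng.random(n_subjects) < right_handed_fraction, "right", "left")
    pain = rng.random(n_subjects) < pain_prevalence  # affected hand: right

    trial_rows, subj_rows = [], []
    for i in range(n_subjects):
        pid = f"S{i + 1:03d}"
        subj_rows.append({
            "participant": pid, "baseline_acuity": base[i, 0],
            "baseline_speed": base[i, 1], "dominant_hand": dominant[i],
            "right_hand_pain": bool(pain[i]),
        })
        for hand in ("left", "right"):
            for direction in ("clockwise", "anticlockwise"):
                for t in range(1, n_trials + 1):
                    if missing_rate > 0 and rng.random() < missing_rate:
                        continue
                    acuity = (base[i, 0]
                              + eff.dominant_gain * (hand == dominant[i])
                              - eff.pain_deficit * (pain[i] and hand == "right")
                              + eff.learning_per_trial * (t - 1)
                              + rng.normal(0.0, acuity_trial_sd))
                    acuity = float(np.clip(acuity, 0.0, 100.0))
                    speed = float(max(base[i, 1] + rng.normal(0.0, speed_trial_sd), 5.0))
                    duration = trace_length_mm / speed
                    n_total = int(round(duration * fps)) + 1
                    trial_rows.append({
                        "participant": pid, "hand": hand,
                        "draw_direction": direction,
                        "anatomical_direction": label_direction(hand, direction),
                        "trial": t,
                        "start_frame": 0, "end_frame": n_total - 1,
                        "duration_s": duration,
                        "acuity_pct": acuity,
                        "speed_arc_mm_s": speed,
                        "speed_nominal_mm_s": speed,
                        "n_frames_total": n_total,
                        "n_frames_detected": n_total,
                        "n_frames_on_line": int(round(acuity / 100.0 * n_total)),
                        "path_length_mm": speed * duration,
                    })
    return pd.DataFrame(trial_rows), pd.DataFrame(subj_rows)
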