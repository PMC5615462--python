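"""Run configuration: every tunable of the scoring pipeline in one place.

Each field has a documented default; unknown keys in a config file are
rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Pipeline configuration with documented defaults.

    Detection
    ---------
    t_abs : minimum red channel value (0-255) for a laser pixel (150).
    t_margin : minimum red dominance R - max(G, B) (60).
    near_max : red value at which a pixel is accepted regardless of margin,
        for saturated white-pink laser cores (245).
    min_dot_area, max_dot_area : connected-component area band-pass in px.
    dark_threshold : grayscale cutoff for line pixels; None = Otsu on the
        board region.
    corner_frame : frame used for the one-off corner detection: "middle"
        (default), "first", or an integer index.  The middle frame is used
        by default because at trial start the dot sits on a terminal corner
        of the line and would bite a hole into that extreme.

    Segmentation
    ------------
    radius_mm : dwell radius around a terminal corner (10 mm).
    dwell_frames : consecutive frames required inside the radius (5).

    Scoring
    -------
    acuity_denominator : "all" counts undetected frames in the trial time
        (off-line), "detected" restricts to frames with a detection.
    speed_mode : "arc_length" (centroid trajectory length / duration) or
        "nominal" (trace length / duration).
    smooth_window : odd moving-average window on the centroid trajectory
        before arc-length integration; 1 = no smoothing (default, keeps the
        measured path commensurate with the raw dot path).
    on_line_tolerance_mm : extra dilation of the line mask in mm.  None
        (default) uses a quarter pixel side at the board scale: dot and
        mask are both sampled at pixel centers, so the discrete overlap
        test is systematically stricter than the continuous line-touching
        region by the mean quantization margin (~0.25 px); this restores
        an unbiased Acuity.
    min_overlap_px : dot/line shared pixels required for "touching" (1).
    interpolate_gaps : bridge runs of <= this many undetected frames by
        linear interpolation of the centroid (0 = never; gaps are logged,
        never silently filled).

    Statistics
    ----------
    icc_form : "consistency" or "agreement" for reported ICC.
    holm : apply Holm correction across condition-level tests.

    seed : master seed for every stochastic component.
    """

    t_abs: int = 150
    t_margin: int = 60
    near_max: int = 245
    min_dot_area: int = 10
    max_dot_area: int = 5000
    dark_threshold: float | None = None
    corner_frame: int | str = "middle"
    radius_mm: float = 10.0
    dwell_frames: int = 5
    acuity_denominator: str = "all"
    speed_mode: str = "arc_length"
    smooth_window: int = 1
    on_line_tolerance_mm: float | None = None
    min_overlap_px: int = 1
    interpolate_gaps: int = 0
    icc_form: str = "consistency"
    holm: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.acuity_denominator not in ("all", "detected"):
            raise ConfigError(f"acuity_denominator: {self.acuity_denominator!r}")
        if self.speed_mode not in ("arc_length", "nominal"):
            raise ConfigError(f"speed_mode: {self.speed_mode!r}")
        if self.icc_form not in ("consistency", "agreement"):
            raise ConfigError(f"icc_form: {self.icc_form!r}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be a positive odd integer")
        if not (isinstance(self.corner_frame, int) or
                self.corner_frame in ("middle", "first")):
            raise ConfigError(f"corner_frame: {self.corner_frame!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a superset; both parse)."""
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for output manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
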