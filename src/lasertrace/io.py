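"""Frame sources and result I/O.

Frames can come from a directory of numbered images, an in-memory array
stack, or (when an imageio video plugin is available) a video container.
All sources expose the same minimal surface: ``fps``, ``n_frames``,
``get(i)`` and iteration in frame order.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import LaserTraceError

SCHEMA_VERSION = "lasertrace-trials-v1"

TRIAL_COLUMNS = [
    "participant", "hand", "draw_direction", "anatomical_direction", "trial",
    "start_frame", "end_frame", "duration_s", "acuity_pct",
    "speed_arc_mm_s", "speed_nominal_mm_s",
    "n_frames_total", "n_frames_detected", "n_frames_on_line", "path_length_mm",
]


class FrameSource:
    """Base class: an ordered, re-iterable stream of color frames."""

    fps: float
    n_frames: int

    def get(self, i: int) -> np.ndarray:
        raise NotImplementedError

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.get(i)

    def __len__(self):
        return self.n_frames


class ArraySource(FrameSource):
    """Frames held in memory as a list/stack of (H, W, 3) arrays."""

    def __init__(self, frames, fps: float):
        self._frames = list(frames)
        if not self._frames:
            raise LaserTraceError("empty frame stack")
        self.fps = float(fps)
        self.n_frames = len(self._frames)

    def get(self, i):
        return self._frames[i]


def _numeric_key(path: Path):
    m = re.search(r"(\d+)", path.stem)
    return (int(m.group(1)) if m else 0, path.name)


class ImageDirectorySource(FrameSource):
    """Directory of numbered frame images (png/jpg/tif), sorted numerically."""

    def __init__(self, directory, fps: float):
        directory = Path(directory)
        exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
        self.paths = sorted((p for p in directory.iterdir() if p.suffix.lower() in exts),
                            key=_numeric_key)
        if not self.paths:
            raise LaserTraceError(f"no frame images found in {directory}")
        self.fps = float(fps)
        self.n_frames = len(self.paths)

    def get(self, i):
        return iio.imread(self.paths[i])


class VideoFileSource(FrameSource):
    """Video container read through imageio (requires an ffmpeg plugin)."""

    def __init__(self, path, fps: float | None = None):
        self.path = Path(path)
        try:
            frames = iio.imread(self.path, index=None)
        except Exception as exc:  # plugin missing or unreadable file
            raise LaserTraceError(
                f"cannot read video {self.path}: {exc}. Install an imageio "
                f"video plugin or supply frames as an image directory."
            ) from exc
        self._frames = np.asarray(frames)
        if self._frames.ndim != 4 or self._frames.shape[0] == 0:
            raise LaserTraceError(f"no frames decoded from {self.path}")
        if fps is None:
            try:
                meta = iio.immeta(self.path)
                fps = float(meta.get("fps", 30.0))
            except Exception:
                fps = 30.0
        self.fps = float(fps)
        self.n_frames = self._frames.shape[0]

    def get(self, i):
        return self._frames[i]


def read_video(path, fps: float | None = None) -> FrameSource:
    """Open a trial recording as a frame source.

    ``path`` may be a video container (decoded via imageio when a plugin is
    available) or a directory of numbered frame images; for directories the
    frame rate must be supplied (default 30 fps, the clinical protocol's
    recording rate).

    Raises
    ------
    LaserTraceError
        For unreadable inputs or directories without frames.
    """
    p = Path(path)
    if not p.exists():
        raise LaserTraceError(f"no such file or directory: {p}")
    if p.is_dir():
        return ImageDirectorySource(p, fps=fps if fps is not None else 30.0)
    return VideoFileSource(p, fps=fps)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_trials_csv(df: pd.DataFrame, path, config=None, source_digest: str | None = None):
    """Write the trial table with a versioned header comment and a manifest.

    The CSV carries a ``# schema`` comment line; a sibling ``.manifest.json``
    records the schema version, the run-config hash and the input digest so
    any output can be traced back to its exact configuration.
    """
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns] + \
           [c for c in df.columns if c not in TRIAL_COLUMNS]
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, columns=cols)
    manifest = {
        "schema": SCHEMA_VERSION,
        "n_rows": int(len(df)),
        "config_digest": config.digest() if config is not None else None,
        "source_digest": source_digest,
    }
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_frames(source: FrameSource, directory, prefix: str = "frame") -> list[Path]:
    """Dump a frame source as numbered PNGs (lossless)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(source.n_frames)))
    paths = []
    for i, frame in enumerate(source):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_debug_overlay(frame, corners=None, dot=None, mask=None, path=None) -> np.ndarray:
    """Render a diagnostic overlay: line mask (blue), corners (yellow), dot (cyan)."""
    img = np.asarray(frame, dtype=np.uint8).copy()
    if mask is not None:
        img[mask] = (0.5 * img[mask] + 0.5 * np.array([0, 0, 255])).astype(np.uint8)
    if corners is not None:
        for pt in corners.as_array():
            x, y = int(round(pt[0])), int(round(pt[1]))
            img[max(y - 3, 0):y + 4, max(x - 3, 0):x + 4] = [255, 255, 0]
    if dot is not None and dot.detected:
        x, y = (int(round(v)) for v in dot.centroid_px)
        img[max(y - 2, 0):y + 3, max(x - 2, 0):x + 3] = [0, 255, 255]
    if path is not None:
        iio.imwrite(path, img)
    return img
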