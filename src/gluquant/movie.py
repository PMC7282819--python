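"""Time-lapse movie container and 16-bit TIFF round-trip I/O.

A :class:`Movie` is a time-ordered stack of 2-D intensity frames with
acquisition metadata (frame interval, optional stimulus time, optional
pixel size).  Frames are stored as a float array; intensities are
non-negative except for derived movies (e.g. walking-average
differences), which set ``allow_negative``.

TIFF files cannot carry the acquisition metadata we need, so
:func:`write_movie_tiff` writes a JSON sidecar (``<path>.json``) next to
every movie recording the frame interval, stimulus time and the gain
used to scale intensities into the 16-bit range.  :func:`read_movie_tiff`
restores the original intensities from the sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Movie", "write_movie_tiff", "read_movie_tiff"]


@dataclass
class Movie:
    frames: np.ndarray
    frame_interval_ms: float
    stimulus_time_ms: float | None = None
    pixel_size_um: float | None = None
    start_time_ms: float = 0.0
    allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, row, col) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if not self.allow_negative and np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.stimulus_time_ms is not None:
            if self.stimulus_time_ms < 0:
                raise ValueError("stimulus_time_ms must be non-negative")
            if self.stimulus_time_ms >= self.duration_ms:
                raise ValueError("stimulus_time_ms must fall within the recording")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    @property
    def frame_onsets_ms(self) -> np.ndarray:
        """Start time of each frame's exposure window."""
        return self.start_time_ms + np.arange(self.n_frames) * self.frame_interval_ms

    @property
    def frame_centers_ms(self) -> np.ndarray:
        """Mid-exposure time of each frame."""
        return self.frame_onsets_ms + 0.5 * self.frame_interval_ms

    @property
    def stimulus_frame(self) -> int | None:
        """Index of the frame whose exposure window contains the stimulus."""
        if self.stimulus_time_ms is None:
            return None
        return int((self.stimulus_time_ms - self.start_time_ms) // self.frame_interval_ms)


def write_movie_tiff(movie: Movie, path: str | Path) -> None:
    """Write a movie as multi-page 16-bit grayscale TIFF plus JSON sidecar.

    Intensities are scaled by a recorded gain so the full 16-bit range is
    used; the gain (and an offset for difference movies that contain
    negative values) is stored in the sidecar for lossless-enough
    round-trips.
    """
    path = Path(path)
    frames = np.asarray(movie.frames, dtype=np.float64)
    offset = float(min(0.0, frames.min()))
    span = float(frames.max() - offset)
    gain = 65535.0 / span if span > 0 else 1.0
    scaled = np.round((frames - offset) * gain).astype(np.uint16)
    tifffile.imwrite(path, scaled, photometric="minisblack")
    meta = {
        "frame_interval_ms": movie.frame_interval_ms,
        "stimulus_time_ms": movie.stimulus_time_ms,
        "pixel_size_um": movie.pixel_size_um,
        "start_time_ms": movie.start_time_ms,
        "gain": gain,
        "offset": offset,
        "allow_negative": movie.allow_negative,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_movie_tiff(
    path: str | Path,
    frame_interval_ms: float | None = None,
    stimulus_time_ms: float | None = None,
) -> Movie:
    """Read a multi-page TIFF movie, applying the JSON sidecar if present.

    Without a sidecar, ``frame_interval_ms`` must be given explicitly.
    """
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frames = frames / meta["gain"] + meta["offset"]
        return Movie(
            frames,
            frame_interval_ms=frame_interval_ms or meta["frame_interval_ms"],
            stimulus_time_ms=(
                stimulus_time_ms
                if stimulus_time_ms is not None
                else meta.get("stimulus_time_ms")
            ),
            pixel_size_um=meta.get("pixel_size_um"),
            start_time_ms=meta.get("start_time_ms", 0.0),
            allow_negative=meta.get("allow_negative", False),
        )
    if frame_interval_ms is None:
        raise ValueError(
            f"{path} has no metadata sidecar; pass frame_interval_ms explicitly"
        )
    return Movie(frames, frame_interval_ms=frame_interval_ms, stimulus_time_ms=stimulus_time_ms)
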