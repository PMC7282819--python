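"""Per-ROI intensity traces and ΔF/F₀ normalization.

``extract_traces`` measures the mean intensity of every ROI in every
frame; ``normalize_dff`` converts raw traces to ΔF/F₀ using the per-ROI
mean over the pre-stimulus baseline window as F₀.  Background
subtraction is folded into the ΔF/F₀ formula (each ROI is its own
baseline); an optional global-background term can be subtracted first
but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .movie import Movie
from .roi import RoiSet

__all__ = ["TraceSet", "extract_traces", "normalize_dff"]


@dataclass
class TraceSet:
    """Per-ROI time series: raw mean intensities and ΔF/F₀."""

    roi_ids: np.ndarray
    times_ms: np.ndarray
    raw: np.ndarray                      # (roi, time)
    dff: np.ndarray | None = None        # (roi, time)
    f0: np.ndarray | None = None         # per ROI
    valid: np.ndarray | None = None      # per ROI, False where f0 <= 0
    frame_interval_ms: float | None = None
    stimulus_time_ms: float | None = None
    frame_onsets_ms: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (roi_id, time_ms, raw[, dff])."""
        n_r, n_t = self.raw.shape
        out = pd.DataFrame({
            "roi_id": np.repeat(self.roi_ids, n_t),
            "time_ms": np.tile(self.times_ms, n_r),
            "raw": self.raw.ravel(),
        })
        if self.dff is not None:
            out["dff"] = self.dff.ravel()
        return out


def extract_traces(movie: Movie, rois: RoiSet,
                   global_background: float = 0.0) -> TraceSet:
    """Mean intensity of each ROI in each frame.

    An empty RoiSet yields an empty TraceSet.  ``global_background``,
    when non-zero, is subtracted from every measurement before any
    further processing.
    """
    if rois.label_image.shape != movie.frame_shape:
        raise ValueError("ROI label image does not match the movie frame shape")
    ids = rois.rois["roi_id"].to_numpy()
    times = movie.frame_centers_ms
    if len(ids) == 0:
        raw = np.zeros((0, movie.n_frames))
    else:
        raw = np.stack([
            ndi.mean(frame, labels=rois.label_image, index=ids)
            for frame in movie.frames
        ], axis=1)
    raw = raw - global_background
    return TraceSet(
        roi_ids=ids, times_ms=times, raw=raw,
        frame_interval_ms=movie.frame_interval_ms,
        stimulus_time_ms=movie.stimulus_time_ms,
        frame_onsets_ms=movie.frame_onsets_ms,
    )


def normalize_dff(traces: TraceSet, baseline_frame_count: int) -> TraceSet:
    """Fill in ΔF/F₀ = (raw − F₀)/F₀ with F₀ the baseline-window mean.

    ROIs whose F₀ is not positive are flagged invalid (``valid`` False)
    and should be excluded from peak analysis; their dff rows are NaN.
    """
    if baseline_frame_count < 1 or baseline_frame_count > traces.raw.shape[1]:
        raise ValueError("baseline window empty or out of range")
    f0 = traces.raw[:, :baseline_frame_count].mean(axis=1)
    valid = f0 > 0
    dff = np.full_like(traces.raw, np.nan, dtype=float)
    dff[valid] = (traces.raw[valid] - f0[valid, None]) / f0[valid, None]
    return TraceSet(
        roi_ids=traces.roi_ids, times_ms=traces.times_ms, raw=traces.raw,
        dff=dff, f0=f0, valid=valid,
        frame_interval_ms=traces.frame_interval_ms,
        stimulus_time_ms=traces.stimulus_time_ms,
        frame_onsets_ms=traces.frame_onsets_ms,
    )
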