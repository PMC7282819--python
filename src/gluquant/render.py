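"""Temporally color-coded maximum projections.

Each pixel of the rendering encodes *when* it was brightest within a
time window (hue, linear red→purple ramp) and *how bright* it got
(value).  This is the standard way to show, in one image, whether
evoked release is synchronous (everything red) or smeared out in time,
and where spontaneous events occurred during a recording.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .movie import Movie

__all__ = ["time_projection", "HUE_START", "HUE_END"]

HUE_START = 0.0   # red, at the start of the window
HUE_END = 0.8     # purple, at the end


def time_projection(movie: Movie, t_start_ms: float, t_end_ms: float,
                    baseline_frame_count: int = 45,
                    noise_floor: float | None = None) -> np.ndarray:
    """Render a hue-coded max projection of background-subtracted signal.

    For every pixel, the frame of maximum signal within
    [t_start_ms, t_end_ms) sets the hue (red at the window start through
    purple at the end) and the maximum amplitude sets the brightness.
    Pixels whose maximum stays below ``noise_floor`` (default: 4x the
    robust sd of the subtracted movie) are black.  Returns an RGB float
    array in [0, 1].
    """
    onsets = movie.frame_onsets_ms
    in_window = (onsets >= t_start_ms) & (onsets < t_end_ms)
    if not in_window.any():
        raise ValueError("no frames inside the requested window")
    baseline_frame_count = min(baseline_frame_count, movie.n_frames - 1)
    baseline = movie.frames[:baseline_frame_count].mean(axis=0)
    signal = movie.frames[in_window] - baseline
    window_times = onsets[in_window]

    peak_idx = signal.argmax(axis=0)
    peak_amp = signal.max(axis=0)
    if noise_floor is None:
        med = np.median(signal)
        noise_floor = 4.0 * 1.4826 * np.median(np.abs(signal - med))

    span = max(window_times[-1] - window_times[0], 1e-9)
    frac = (window_times[peak_idx] - window_times[0]) / span
    hue = HUE_START + (HUE_END - HUE_START) * frac
    amp_max = peak_amp.max()
    value = np.clip(peak_amp / amp_max, 0.0, 1.0) if amp_max > 0 else np.zeros_like(peak_amp)
    value[peak_amp < noise_floor] = 0.0
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)
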