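"""Synthetic fluorescence data with known ground truth.

Generates the three classes of input the analysis pipeline consumes:

* evoked iGluSnFR movies — 150 frames at 10 ms/frame, single field
  stimulus 500 ms after the first frame; each bouton releases glutamate
  with a configurable probability, drawing its latency from a
  synchronous (truncated-Gaussian) / asynchronous (exponential) mixture;
* spontaneous (TTX) movies — 300 frames at 200 ms/frame, per-bouton
  homogeneous Poisson miniature-event trains;
* single-exponential decay time courses (protein-turnover emulation);
* two-channel spot images with a known colocalized fraction.

Every generator is a pure function of ``(config, seed)``.  Events are
rendered as Gaussian spots whose temporal profile is the sensor impulse
response of :func:`transient_kernel`; frame values are the *mean* of the
kernel over each frame's exposure window (camera integration), which is
what makes 200 ms-exposure movies phase-robust.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    EVOKED_FRAME_MS,
    EVOKED_N_FRAMES,
    EVOKED_STIMULUS_MS,
    SPONT_FRAME_MS,
    SPONT_N_FRAMES,
    SYNC_WINDOW_MS,
    SimConfig,
)
from .movie import Movie

__all__ = [
    "transient_kernel",
    "kernel_time_to_peak",
    "classify_event_time",
    "place_boutons",
    "simulate_evoked_movie",
    "simulate_spontaneous_movie",
    "simulate_decay_series",
    "simulate_two_channel",
]

GT_COLUMNS = ["bouton_id", "center_row", "center_col", "event_time_ms",
              "latency_class", "amplitude_dff"]


# ---------------------------------------------------------------------------
# sensor impulse response

def _check_kernel_params(rise_ms: float, decay_ms: float) -> None:
    if rise_ms <= 0 or decay_ms <= 0:
        raise ValueError("kernel time constants must be positive")


def kernel_time_to_peak(rise_ms: float, decay_ms: float) -> float:
    """Time at which the un-normalized kernel attains its maximum.

    Setting d/dt[(1 - e^(-t/r)) e^(-t/d)] = 0 gives t* = r ln(1 + d/r).
    """
    _check_kernel_params(rise_ms, decay_ms)
    return rise_ms * np.log1p(decay_ms / rise_ms)


def _kernel_peak(rise_ms: float, decay_ms: float) -> float:
    t_peak = kernel_time_to_peak(rise_ms, decay_ms)
    return (1.0 - np.exp(-t_peak / rise_ms)) * np.exp(-t_peak / decay_ms)


def transient_kernel(t_ms, rise_ms: float, decay_ms: float):
    """Sensor impulse response, normalized to a maximum of 1.

    ``k(t) = (1 - exp(-t/rise)) exp(-t/decay) / k_max`` for t >= 0 and 0
    for t < 0.  Scalar in, scalar out; array in, array out.
    """
    _check_kernel_params(rise_ms, decay_ms)
    t = np.asarray(t_ms, dtype=float)
    value = np.where(
        t >= 0,
        (1.0 - np.exp(-np.clip(t, 0, None) / rise_ms))
        * np.exp(-np.clip(t, 0, None) / decay_ms),
        0.0,
    ) / _kernel_peak(rise_ms, decay_ms)
    if np.isscalar(t_ms):
        return float(value)
    return value


def _kernel_integral(x, rise_ms: float, decay_ms: float):
    """Integral of the *normalized* kernel from 0 to x (x >= 0)."""
    q = 1.0 / (1.0 / rise_ms + 1.0 / decay_ms)
    x = np.clip(np.asarray(x, dtype=float), 0.0, None)
    raw = decay_ms * (1.0 - np.exp(-x / decay_ms)) - q * (1.0 - np.exp(-x / q))
    return raw / _kernel_peak(rise_ms, decay_ms)


def _frame_means(event_time_ms: float, onsets_ms: np.ndarray, interval_ms: float,
                 rise_ms: float, decay_ms: float) -> np.ndarray:
    """Mean of the normalized kernel over each frame's exposure window."""
    a = onsets_ms - event_time_ms
    b = a + interval_ms
    return (
        _kernel_integral(b, rise_ms, decay_ms)
        - _kernel_integral(a, rise_ms, decay_ms)
    ) / interval_ms


# ---------------------------------------------------------------------------
# ground-truth bookkeeping

def classify_event_time(event_time_ms: float, stimulus_time_ms: float | None) -> str:
    """Latency class of a release event.

    Post-stimulus events within ``SYNC_WINDOW_MS`` (closed at 10 ms) are
    synchronous, later events asynchronous.  Events in movies without a
    stimulus — or Poisson background events occurring before the
    stimulus — are spontaneous.
    """
    if stimulus_time_ms is None:
        return "spontaneous"
    latency = event_time_ms - stimulus_time_ms
    if latency < 0:
        return "spontaneous"
    return "synchronous" if latency <= SYNC_WINDOW_MS else "asynchronous"


def place_boutons(config: SimConfig, rng: np.random.Generator,
                  margin_px: int = 10, max_attempts: int = 10_000) -> np.ndarray:
    """Rejection-sample integer bouton centers with minimum separation.

    Centers sit on the pixel grid, at least ``margin_px`` from every
    border and at least 4 sigma apart.  Raises if the field cannot
    accommodate ``n_boutons`` within ``max_attempts`` draws per bouton.
    """
    rows, cols = config.image_shape
    if rows <= 2 * margin_px or cols <= 2 * margin_px:
        raise ValueError("image too small for the placement margin")
    min_sep2 = config.min_separation_px ** 2
    centers: list[tuple[int, int]] = []
    for _ in range(config.n_boutons):
        for _attempt in range(max_attempts):
            r = int(rng.integers(margin_px, rows - margin_px))
            c = int(rng.integers(margin_px, cols - margin_px))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise ValueError(
                f"could not place {config.n_boutons} boutons at >= "
                f"{config.min_separation_px:.1f} px separation"
            )
    return np.asarray(centers, dtype=int)


def _gaussian_patch(sigma_px: float) -> tuple[np.ndarray, int]:
    radius = int(np.ceil(4 * sigma_px))
    ax = np.arange(-radius, radius + 1)
    patch = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_px ** 2))
    return patch, radius


def _render_events(frames: np.ndarray, events: pd.DataFrame, config: SimConfig,
                   onsets_ms: np.ndarray, interval_ms: float) -> None:
    """Add every ground-truth event into ``frames`` in place."""
    patch, radius = _gaussian_patch(config.bouton_sigma_px)
    n_rows, n_cols = config.image_shape
    for ev in events.itertuples(index=False):
        profile = ev.amplitude_dff * config.baseline_intensity * _frame_means(
            ev.event_time_ms, onsets_ms, interval_ms,
            config.transient_rise_ms, config.transient_decay_ms,
        )
        active = np.nonzero(profile > 1e-6)[0]
        if active.size == 0:
            continue
        r, c = int(ev.center_row), int(ev.center_col)
        r0, r1 = max(0, r - radius), min(n_rows, r + radius + 1)
        c0, c1 = max(0, c - radius), min(n_cols, c + radius + 1)
        sub = patch[r0 - (r - radius): r1 - (r - radius),
                    c0 - (c - radius): c1 - (c - radius)]
        frames[active, r0:r1, c0:c1] += profile[active][:, None, None] * sub[None]


def _finalize_movie(frames: np.ndarray, config: SimConfig, interval_ms: float,
                    onsets_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if config.bleach_tau_ms is not None:
        centers = onsets_ms + 0.5 * interval_ms
        frames *= np.exp(-centers / config.bleach_tau_ms)[:, None, None]
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return frames


def _poisson_background(config: SimConfig, centers: np.ndarray,
                        duration_ms: float, rng: np.random.Generator) -> list[tuple]:
    """Homogeneous Poisson miniature events for every bouton."""
    rows = []
    rate_per_ms = config.spontaneous_rate_per_bouton_per_min / 60_000.0
    for b, (r, c) in enumerate(centers):
        n = rng.poisson(rate_per_ms * duration_ms)
        for t in np.sort(rng.uniform(0.0, duration_ms, size=n)):
            rows.append((b, r, c, float(t)))
    return rows


# ---------------------------------------------------------------------------
# movie generators

def simulate_evoked_movie(config: SimConfig) -> tuple[Movie, pd.DataFrame]:
    """Simulate a single-stimulus movie (150 frames x 10 ms, stimulus at 500 ms).

    Each bouton releases with ``release_probability``; latencies come
    from the truncated-Gaussian (synchronous) / exponential
    (asynchronous) mixture.  Spontaneous Poisson events are superimposed
    at ``spontaneous_rate_per_bouton_per_min``.  Returns the movie and
    the ground-truth event table.
    """
    rng = np.random.default_rng(config.seed)
    centers = place_boutons(config, rng)
    duration_ms = EVOKED_N_FRAMES * EVOKED_FRAME_MS

    rows = []
    for b, (r, c) in enumerate(centers):
        if rng.uniform() < config.release_probability:
            if rng.uniform() < config.sync_fraction:
                latency = -1.0
                while latency < 0:
                    latency = rng.normal(config.sync_latency_mean_ms,
                                         config.sync_latency_sd_ms)
            else:
                latency = rng.exponential(config.async_latency_tau_ms)
            rows.append((b, r, c, EVOKED_STIMULUS_MS + latency))
    rows.extend(_poisson_background(config, centers, duration_ms, rng))

    events = pd.DataFrame(rows, columns=GT_COLUMNS[:4])
    events["latency_class"] = [
        classify_event_time(t, EVOKED_STIMULUS_MS) for t in events["event_time_ms"]
    ]
    events["amplitude_dff"] = config.transient_amplitude_dff
    events = events[events["event_time_ms"] < duration_ms].reset_index(drop=True)

    frames = np.full((EVOKED_N_FRAMES, *config.image_shape),
                     config.baseline_intensity, dtype=np.float64)
    onsets = np.arange(EVOKED_N_FRAMES) * EVOKED_FRAME_MS
    _render_events(frames, events, config, onsets, EVOKED_FRAME_MS)
    frames = _finalize_movie(frames, config, EVOKED_FRAME_MS, onsets, rng)
    movie = Movie(frames, frame_interval_ms=EVOKED_FRAME_MS,
                  stimulus_time_ms=EVOKED_STIMULUS_MS)
    return movie, events


def simulate_spontaneous_movie(config: SimConfig) -> tuple[Movie, pd.DataFrame]:
    """Simulate a stimulus-free TTX movie (300 frames x 200 ms).

    Per-bouton event times are a homogeneous Poisson process at
    ``spontaneous_rate_per_bouton_per_min``.
    """
    rng = np.random.default_rng(config.seed)
    centers = place_boutons(config, rng)
    duration_ms = SPONT_N_FRAMES * SPONT_FRAME_MS

    rows = _poisson_background(config, centers, duration_ms, rng)
    events = pd.DataFrame(rows, columns=GT_COLUMNS[:4])
    events["latency_class"] = "spontaneous"
    events["amplitude_dff"] = config.transient_amplitude_dff

    frames = np.full((SPONT_N_FRAMES, *config.image_shape),
                     config.baseline_intensity, dtype=np.float64)
    onsets = np.arange(SPONT_N_FRAMES) * SPONT_FRAME_MS
    _render_events(frames, events, config, onsets, SPONT_FRAME_MS)
    frames = _finalize_movie(frames, config, SPONT_FRAME_MS, onsets, rng)
    movie = Movie(frames, frame_interval_ms=SPONT_FRAME_MS, stimulus_time_ms=None)
    return movie, events


# ---------------------------------------------------------------------------
# non-movie generators

def simulate_decay_series(tau: float, amplitude: float, plateau: float,
                          times, noise_sd: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Single-exponential-with-plateau time course.

    ``value(t) = plateau + (amplitude - plateau) exp(-t/tau)`` plus
    Gaussian noise; emulates a normalized band-intensity turnover curve.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    values = plateau + (amplitude - plateau) * np.exp(-times / tau)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0.0, noise_sd, times.size)
    return pd.DataFrame({"time": times, "value": values})


def simulate_two_channel(image_shape: tuple[int, int], n_spots: int,
                         colocalized_fraction: float, noise_sd: float,
                         seed: int = 0, spot_sigma_px: float = 2.0,
                         spot_intensity: float = 100.0,
                         ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Two-channel spot images with a known colocalized fraction.

    Channel 1 holds all ``n_spots``; channel 2 holds the colocalized
    subset at identical centers plus ``(1 - fraction) * n_spots``
    independent spots.  Spot amplitudes vary uniformly over
    [0.5, 1.5] x ``spot_intensity``; each channel gets independent
    Gaussian noise.  Returns (ch1, ch2, truth table).
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if not 0.0 <= colocalized_fraction <= 1.0:
        raise ValueError("colocalized_fraction must be in [0, 1]")
    rows, cols = image_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("image_shape entries must be positive")
    rng = np.random.default_rng(seed)
    patch, radius = _gaussian_patch(spot_sigma_px)

    def add_spot(img, r, c, amp):
        r0, r1 = max(0, r - radius), min(rows, r + radius + 1)
        c0, c1 = max(0, c - radius), min(cols, c + radius + 1)
        img[r0:r1, c0:c1] += amp * patch[r0 - (r - radius): r1 - (r - radius),
                                         c0 - (c - radius): c1 - (c - radius)]

    n_coloc = int(round(colocalized_fraction * n_spots))
    ch1 = np.zeros(image_shape)
    ch2 = np.zeros(image_shape)
    records = []
    pos = rng.integers([0, 0], [rows, cols], size=(n_spots, 2))
    amps = spot_intensity * rng.uniform(0.5, 1.5, size=n_spots)
    for i, ((r, c), amp) in enumerate(zip(pos, amps)):
        add_spot(ch1, r, c, amp)
        if i < n_coloc:
            add_spot(ch2, r, c, amp)
        records.append({"spot_id": i, "row": int(r), "col": int(c),
                        "amplitude": float(amp), "colocalized": i < n_coloc,
                        "channel": "both" if i < n_coloc else "ch1"})
    extra_pos = rng.integers([0, 0], [rows, cols], size=(n_spots - n_coloc, 2))
    extra_amp = spot_intensity * rng.uniform(0.5, 1.5, size=n_spots - n_coloc)
    for j, ((r, c), amp) in enumerate(zip(extra_pos, extra_amp)):
        add_spot(ch2, r, c, amp)
        records.append({"spot_id": n_spots + j, "row": int(r), "col": int(c),
                        "amplitude": float(amp), "colocalized": False,
                        "channel": "ch2"})
    if noise_sd > 0:
        ch1 += rng.normal(0.0, noise_sd, size=image_shape)
        ch2 += rng.normal(0.0, noise_sd, size=image_shape)
    return ch1, ch2, pd.DataFrame.from_records(records)
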