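"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic-data generator in
one validated, immutable record so that a simulation is a pure function
of ``(config, seed)``.  The defaults describe the imaging experiments the
generator emulates:

* evoked protocol — 150 frames at 10 ms/frame, one field stimulus 500 ms
  after the first frame;
* spontaneous protocol — 300 frames at 200 ms/frame, no stimulus, action
  potentials silenced so only miniature events remain.

The default optics put the per-event peak signal-to-noise ratio at the
center pixel near 8 for the evoked protocol
(``baseline_intensity * transient_amplitude_dff / noise_sd``).
:meth:`SimConfig.for_spontaneous` keeps the photon flux constant while
lengthening the exposure 20-fold, scaling the baseline by 20 and the
shot-noise-like sd by sqrt(20).
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["SimConfig", "EVOKED_N_FRAMES", "EVOKED_FRAME_MS", "EVOKED_STIMULUS_MS",
           "SPONT_N_FRAMES", "SPONT_FRAME_MS", "SYNC_WINDOW_MS"]

# Acquisition constants of the two imaging protocols.
EVOKED_N_FRAMES = 150
EVOKED_FRAME_MS = 10.0
EVOKED_STIMULUS_MS = 500.0
SPONT_N_FRAMES = 300
SPONT_FRAME_MS = 200.0

# A release event peaking within this window after the stimulus counts
# as synchronous (closed boundary: exactly 10 ms is synchronous).
SYNC_WINDOW_MS = 10.0


class SimConfig(BaseModel):
    """Parameters of the synthetic fluorescence-movie generator."""

    model_config = ConfigDict(frozen=True)

    image_shape: tuple[int, int] = (128, 128)
    n_boutons: int = Field(default=64, gt=0)
    bouton_sigma_px: float = Field(default=2.5, gt=0)
    baseline_intensity: float = Field(default=100.0, gt=0)
    release_probability: float = Field(default=0.6, ge=0, le=1)
    sync_fraction: float = Field(default=0.9, ge=0, le=1)
    sync_latency_mean_ms: float = Field(default=2.0, gt=0)
    sync_latency_sd_ms: float = Field(default=2.0, gt=0)
    async_latency_tau_ms: float = Field(default=50.0, gt=0)
    spontaneous_rate_per_bouton_per_min: float = Field(default=1.0, ge=0)
    transient_amplitude_dff: float = Field(default=0.8, gt=0)
    transient_rise_ms: float = Field(default=2.0, gt=0)
    transient_decay_ms: float = Field(default=80.0, gt=0)
    noise_sd: float = Field(default=10.0, ge=0)
    bleach_tau_ms: float | None = Field(default=None, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_shape(self) -> "SimConfig":
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape entries must be positive")
        return self

    @property
    def min_separation_px(self) -> float:
        """Minimum center-to-center bouton distance (4 sigma)."""
        return 4.0 * self.bouton_sigma_px

    @classmethod
    def for_spontaneous(cls, **overrides) -> "SimConfig":
        """Config for the spontaneous (TTX) protocol at constant photon flux.

        The 200 ms exposure collects 20x the photons of the 10 ms evoked
        exposure, so the baseline scales by 20 and the noise sd by
        sqrt(20).
        """
        scale = SPONT_FRAME_MS / EVOKED_FRAME_MS
        defaults = dict(
            baseline_intensity=100.0 * scale,
            noise_sd=10.0 * math.sqrt(scale),
        )
        defaults.update(overrides)
        return cls(**defaults)
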