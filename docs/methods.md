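# Methods

`gluquant` implements an optical quantal analysis of glutamate-sensor
(iGluSnFR-style) fluorescence movies: finding release sites after a
field stimulus, extracting ΔF/F₀ responses, classifying release as
synchronous/asynchronous/spontaneous, detecting miniature glutamate
transients (mGTs) under TTX, fitting protein-turnover kinetics, and
quantifying two-channel colocalization. Because raw recordings of this
kind are rarely deposited, every stage is validated against a
synthetic-data generator with exact ground truth. This note records
the models, the defaults and their reasoning, the numerical choices,
and what the synthetic validation does and does not establish.

## The synthetic imaging model

**Acquisition protocols.** Two fixed protocols mirror common practice:
evoked — 150 frames at 10 ms/frame with a single field stimulus 500 ms
after the first frame; spontaneous — 300 frames at 200 ms/frame with
no stimulus (action potentials assumed silenced). The stimulus falls
exactly on a frame boundary.

**Sensor impulse response.** A release event at time *t₀* produces a
fluorescence transient

    k(t) = (1 − e^{−(t−t₀)/τ_rise}) · e^{−(t−t₀)/τ_decay},

normalized to a peak of 1 (peak at `τ_rise · ln(1 + τ_decay/τ_rise)`,
≈ 7.4 ms at the defaults). Defaults `τ_rise = 2 ms`, `τ_decay = 80 ms`
are plausible for a surface-displayed glutamate sensor at ~34 °C; they
are placeholders recorded in the configuration, never hard-coded into
the analysis, and should be re-measured for any real rig.

**Camera integration.** A frame's value is the *mean* of the kernel
over the frame's exposure window (closed-form integral), not a point
sample. This matters at 200 ms exposures, where a point sample would
make event amplitudes depend violently on the event's phase within the
frame; integration caps the phase dependence at roughly a factor of two
(an event split across two exposures).

**Space, amplitude, noise.** Each bouton is a Gaussian spot of
`bouton_sigma_px = 2.5` px placed on the pixel grid by rejection
sampling with a minimum separation of 4σ and a 10 px border margin. At
a typical 60×/1.49 NA TIRF-style rig with a 6.5 µm-pixel sCMOS camera
(~0.11 µm/px), a glutamate release plume of σ ≈ 0.3 µm is ~2.5 px; a
markedly smaller spot would also be invisible to the 10-pixel particle
size filter the ROI workflow applies, so smaller values are not
operationally meaningful study conditions. Events add
`amplitude_dff × baseline_intensity × k(t)` scaled by the spot profile;
noise is i.i.d. Gaussian per pixel per frame (a shot-noise
approximation; an intensity-scaled variant is not modeled), and frames
are clipped at zero. Evoked defaults `baseline 100, amplitude 0.8,
noise sd 10` put the center-pixel peak SNR at 8. The spontaneous
protocol keeps photon flux constant at 20× the exposure:
`SimConfig.for_spontaneous()` scales the baseline by 20 and the noise
sd by √20.

**Release model.** Under stimulation each bouton releases at most once
with probability `release_probability` (default 0.6); the latency is a
mixture: with probability `sync_fraction` a Gaussian (mean 2 ms, sd
2 ms, truncated at 0), otherwise an exponential with mean 50 ms.
Ground-truth labels use the field's 10 ms rule: latency ≤ 10 ms (closed
boundary) is synchronous, later is asynchronous. An independent
homogeneous Poisson process per bouton (`spontaneous_rate_per_bouton_per_min`,
default 1) adds miniature events; in stimulated movies such events are
labeled by the same 10 ms rule when they follow the stimulus and as
spontaneous when they precede it. The clamped/unclamped phenotype is
emulated by sweeping `sync_fraction` down while sweeping the
spontaneous rate up; no mechanistic coupling is built in.

What the generator deliberately omits: Airyscan-style optics, axial
structure, drift, bleaching by default (an optional exponential bleach
is available), vesicle-pool depletion, multi-release per stimulus, and
intensity-dependent noise. Passing the validation suite therefore
demonstrates correctness of the *analysis* under the stated imaging
model, not robustness to every artifact of real recordings.

## ROI discovery (evoked movies)

The chain follows the classic interactive workflow for this assay:
baseline average of the first 45 frames (a 50 ms guard before the
stimulus) → maximum projection minus baseline → band-pass by
subtracting a circular mean filter (radius 10 px, edge replication) →
threshold → binary watershed → particle filtering (8-connected
components, area ≥ 10 px with interior holes filled, border-touching
components removed). Frame indexing is 0-based internally; reported
times are ms from recording start.

Two points were genuinely open and are resolved as follows:

* **Mean filter, not rolling ball.** The band-pass subtracts a
  circular-neighborhood mean; the radius (10 px) follows the executable
  convention of the interactive ImageJ workflow this chain mirrors.
* **Deterministic replacement of the interactive threshold.** The
  automatic method is isodata (the iterative mean-of-means rule behind
  the common "default" auto-threshold), with `otsu` and `manual`
  alternatives. An automatic histogram split is meaningless on a
  signal-free image — isodata on a pure-noise response image marks
  roughly half the pixels — so `detect_rois` additionally enforces a
  noise floor: the applied threshold is never below
  `median + 3 × robust sd` of the band-passed response (robust sd =
  1.4826 × MAD). This is exactly the judgment the interactive step
  delegated to a human, made deterministic and logged per run
  (`threshold_auto_value` vs `threshold_value`); it can be disabled
  with `noise_floor_sigma=0`. With it, a pure-noise movie yields zero
  ROIs while signal movies are unaffected (the isodata threshold on a
  real response sits above the floor or within a few percent of it).

The binary watershed seeds basins at the regional maxima of the exact
Euclidean distance transform and separates distinct basins with
one-pixel background lines; objects with a single (possibly plateau)
maximum pass through unchanged.

## Traces and ΔF/F₀

Per-ROI raw traces are plain means over the ROI's pixels per frame.
F₀ is the per-ROI mean over the baseline window, and
ΔF/F₀ = (raw − F₀)/F₀; background subtraction is thereby folded into
the normalization (the workflow measures only ROI means; a global
background constant can optionally be subtracted first). ROIs with
non-positive F₀ are flagged and excluded from peak analysis.
Normalization is per-trace, and is invariant to any uniform gain on
the movie.

## Peak timing and release-mode classification

Each ROI contributes one peak per trial: the global maximum of its
ΔF/F₀ trace, ties broken to the earliest frame. The peak's latency is
the *onset* time of the exposure window containing the maximum, minus
the stimulus time. Since the stimulus sits on a frame boundary,
latencies are quantized to multiples of the 10 ms frame interval, and
the ≤ 10 ms synchronous criterion admits the first two post-stimulus
exposure windows.

The onset convention is deliberate. The sensor peaks ~7.4 ms after
release, so a release at latency ℓ peaks at ℓ + 7.4 ms; with
mid-exposure timestamps, a zero-latency release would often be stamped
15 ms and misclassified as asynchronous — a systematic error of the
timestamp convention, not of the biology. The onset time is a lower
bound on the true peak time that offsets the sensor delay; on
simulated data at a 0.8 synchronous mixture the recovered synchronous
fraction tracks the realized ground-truth fraction to within ~0.02.
Latencies are lower bounds; they should be read as bin labels, not as
sub-frame timing.

Histograms use half-open 10 ms bins `[edge, edge + 10)`, with
edge-exact peaks assigned rightward. The synchronous fraction is
synchronous/(synchronous + asynchronous); pre-stimulus peaks are
reported but excluded from the denominator.

**Group comparison.** Kruskal–Wallis H (tie-corrected, via
`scipy.stats.kruskal`) with Dunn's pairwise z statistics on mean ranks
using the same tie correction; two-sided p values are Bonferroni
multiplied by the number of comparisons performed (the behavior of the
commonly used analysis software), with Holm available by flag.

## Miniature-event detection (spontaneous movies)

**Walking-average subtraction.** The dynamic background is a running
mean over `window_frames = 4` frames (the window is an inference from
the three leading frames the classic ImageJ recipe discards, and stays
configurable): `diff[t] = frames[t+3] − mean(frames[t:t+4])`, output
length n − 3, timestamps preserved. A spatially uniform constant
offset cancels exactly.

**Detector.** Manual counting is replaced by an explicit detector.
Candidates are 3×3×3 local maxima of the spatially Gaussian-smoothed
difference movie (`smooth_sigma_px` defaults to the spot sigma — a
matched filter) that are significant at `snr_threshold = 4` times the
robust temporal sd of the smoothed trace at that pixel. A candidate
is retained only if its *raw* difference amplitude (`peak_df`, the
quantity reported as ΔF) also reaches 4× the robust sd of the raw
pixel trace — the reported `snr`. The two conditions answer different
questions (is there a spot-shaped event here? is this pixel's
excursion individually significant?) and are nearly independent under
noise, so their conjunction is what keeps the default threshold of 4
quiet: a 128×128×60 s pure-noise movie yields ~0.1 false positives per
FOV-minute, versus ~30/min for either condition alone. Robust sds use
1.4826 × MAD over the whole trace, which sparse real events do not
shift appreciably. Candidates within `min_separation_ms = 250` and one
spot footprint (3σ) of a larger peak are merged.

**Validation plot.** `background_roi_validation` re-measures each
event and an off-center control pixel at the matched event frame,
giving the amplitude-vs-SNR separation table; the control is sampled
at the event's own frame so its ΔF distribution is symmetric about
zero and pairs are directly comparable (a max over the whole series
would be positively biased by construction). The reported separation
statistic is min(event SNR) − max(background SNR).

**Rates and dead time.** `event_rate` scales counts to per-FOV or
per-bouton per minute over the *observed* duration (the difference
movie is window − 1 frames shorter than the recording). The
walking-average suppresses an event that follows another at the same
site within about the averaging window, i.e. a per-site dead time
δ = (window − 1) × frame interval = 0.6 s at defaults. The optional
non-paralyzable correction `r/(1 − r·δ)` (standard in photon counting)
removes the resulting censoring; δ is derived from the window, not
fitted, and predicts the simulated detection losses across
0.2–5 events/bouton/min (−0.2% to −4.8%). The correction is off in the
bare `event_rate` contract and enabled wherever the window is known
(CLI, validation studies). Two releases within one exposure at one
site remain one optical event; no estimator can undo that.

## Turnover kinetics and regression

Decay curves are fitted by least squares to
`value(t) = C + (A − C)·e^{−t/τ}` with τ > 0 (trust-region fit,
parameter tolerance 1e-8; initialization A from the first point, C
from the minimum, τ from a log-linear fit of value − C). The plateau
floats by default — normalized turnover data can retain a long-lived
fraction — with a fix-to-zero flag for curves known to decay fully
(then 3 points suffice instead of 4). Half-life is definitionally
τ·ln 2; the reporting helper rounds to the integer minute, matching
how such values are quoted (τ = 41 min → 28 min; τ = 165 min →
114 min), while raw values are always retained. A series that ends
higher than it starts is refused under the decay model unless
explicitly forced. Fits are covariant under time-unit rescaling (τ and
t½ scale, R² invariant).

Identifiability caveat: with a floating plateau, three-parameter
exponential fits lose the plateau when the data cover only the flat
tail or when noise reaches ~10% — occasional replicates diverge toward
a near-linear fit with a meaningless plateau. On a τ = 3.85-day curve
with plateau 0.5 sampled daily over days 0–11, the fitted plateau
exceeds 0.3 in ~97% of replicates at 5% noise but only ~81% at 10%;
the validation suite asserts the property in the identifiable regime
and users fitting noisier data should fix the plateau or extend the
sampling.

`linear_fit` is ordinary least squares with the two-sided t test
(n − 2 df) for zero slope, as used for condition-level
synchronous-vs-spontaneous regressions.

## Colocalization

Pearson's correlation is computed over all pixels and over pixels
above the Costes automatic threshold. The Costes pair is found by
orthogonal (total least squares) regression of channel 2 on channel 1
followed by a downward scan over up to 256 candidate levels of
channel 1: the threshold is the largest T whose below-threshold pixels
(ch1 < T and ch2 < aT + b) have PCC ≤ 0. Perfectly correlated inputs
never satisfy the criterion; the thresholds then fall to the channel
minima with a warning. The thresholded PCC uses pixels above threshold
in *either* channel (the common plugin convention; a both-channels
variant is behind a flag) and is flagged unreliable below 10 usable
pixels. Region handling accepts an explicit rectangle list or a seeded
random-rectangle sampler and reports per-rectangle plus pooled values.
On synthetic spot pairs the thresholded PCC rises strictly with the
generator's colocalized fraction (≈ −0.6 at fraction 0 to ≈ 0.95 at 1),
reproducing the qualitative redistribution readout the method is used
for; no absolute PCC values are claimed.

## Rendering

`time_projection` encodes, per pixel, the time of the maximal
background-subtracted signal within a window as hue (linear HSV ramp,
red 0.0 at the window start to purple 0.8 at the end — a plain
linear ramp, since conventions for these renderings vary) and the
maximal amplitude as brightness, with sub-noise-floor pixels black
(default floor: 4 robust sd of the subtracted movie). Presets: evoked
— ΔF/F₀-style window of 100 ms after the stimulus; spontaneous — ΔF
over the full recording.

## Problem sizes in the validation suite

The shipped validation studies use: 5 default evoked movies
(128×128, 64 boutons) for ROI precision/recall; ~25 movies pooling
≥ 1000 evoked events for classification recovery; 200 replicates for
kinetics recovery; 50 movies × 3 rates (64×64, 10 boutons) plus
15 movies/condition for the 2.4-fold contrast; 100 pure-noise movies
(128×128) and 1000 null simulations for the calibration checks. These
sizes give standard errors comfortably inside the tolerances being
asserted while keeping a full run in the minutes range on one core.
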