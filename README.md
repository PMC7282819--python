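# gluquant

Optical quantal analysis of glutamate-sensor fluorescence movies.

Surface-displayed glutamate sensors (iGluSnFR and relatives) report
neurotransmitter release as brief fluorescence transients at synaptic
boutons, making it possible to measure — in the same cultures — both
*evoked* release after a field stimulus and *spontaneous* miniature
release under TTX. `gluquant` packages the full analysis chain this
kind of experiment needs, for neuroscientists quantifying release
modes from time-lapse TIFF movies:

* **ROI discovery** in single-stimulus movies — baseline/maximum
  projection difference, circular mean-filter band-pass, automatic
  (isodata) thresholding, binary watershed, and particle filtering;
* **ΔF/F₀ trace extraction** per ROI with pre-stimulus baselines;
* **release-mode classification** — one ΔF/F₀ peak per ROI, binned at
  10 ms; a peak within 10 ms of the stimulus is *synchronous*, later
  peaks are *asynchronous*: the synchronous fraction is
  `n_sync / (n_sync + n_async)`;
* **miniature-event (mGT) detection** under TTX via walking-average
  background subtraction and a dual SNR criterion, with rates in
  events/FOV/min or events/bouton/min;
* **turnover kinetics** — least-squares fits of
  `value(t) = C + (A − C)·e^(−t/τ)` with half-life `t½ = τ·ln 2`, and
  ordinary least-squares regression with a zero-slope t test;
* **colocalization** — Pearson's r with Costes automatic thresholding;
* **synthetic data** — a ground-truth simulator of all three
  experiment classes (evoked movies, TTX movies, decay curves,
  two-channel images), so every stage has a parameter-recovery test.

Statistical comparisons between conditions use the Kruskal–Wallis test
with Dunn's multiple-comparison correction.

## Worked example

Simulate a default evoked experiment (128×128 px, 64 boutons, 150
frames at 10 ms, stimulus at 500 ms, peak SNR ≈ 8) and analyze it:

```python
from gluquant import (SimConfig, simulate_evoked_movie, detect_rois,
                      extract_traces, normalize_dff, detect_peaks,
                      synchronous_fraction)

movie, truth = simulate_evoked_movie(SimConfig(seed=0, sync_fraction=0.8))
rois, log = detect_rois(movie)
traces = normalize_dff(extract_traces(movie, rois), baseline_frame_count=45)
peaks = detect_peaks(traces)
print(len(rois), round(log["threshold_value"], 2))
print(round(synchronous_fraction(peaks), 3),
      round((truth.latency_class == "synchronous").mean()
            / (truth.latency_class != "spontaneous").mean(), 3))
```

prints

```
40 13.99
0.775 0.78
```

— 40 ROIs found (40 of the 64 boutons released in this draw; all are
recovered, none are spurious; the applied threshold was 13.99), and a
recovered synchronous fraction of 0.775 against a realized
ground-truth fraction of 0.78 for this movie.

The same pipeline is scriptable from the shell:

```sh
gluquant simulate --kind evoked --out sim --seed 0
gluquant detect-evoked --movie sim/movie.tif --out analysis
gluquant render --movie sim/movie.tif --out projection.png --preset evoked
```

`analysis/summary.csv` then contains the ROI count and synchronous
fraction; every output directory also receives the run's full
configuration (`run_config.txt`, `run_log.json`).

Half-life arithmetic matches the values such experiments quote: a
cleavage time constant of τ = 41 min gives a reported half-life of
28 min, and τ = 165 min gives 114 min:

```python
from gluquant.kinetics import reported_half_life
reported_half_life(41.0), reported_half_life(165.0)   # (28.0, 114.0)
```

See `docs/methods.md` for the models, defaults, and numerical choices.

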