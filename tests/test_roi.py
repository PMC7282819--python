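"""ROI-discovery chain: projections, band-pass, threshold, watershed, labeling."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from gluquant.config import SimConfig
from gluquant.movie import Movie
from gluquant.roi import (
    EIGHT_CONNECTED,
    bandpass,
    baseline_projection,
    detect_rois,
    label_rois,
    match_rois_to_boutons,
    response_image,
    threshold_auto,
    watershed_split,
)
from gluquant.synthetic import simulate_evoked_movie

from conftest import make_movie


# ---------------------------------------------------------------------------
# independent oracles

def mean_filter_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Circular mean filter by direct neighborhood sums with edge replication."""
    rows, cols = image.shape
    offsets = [(dr, dc)
               for dr in range(-radius, radius + 1)
               for dc in range(-radius, radius + 1)
               if dr * dr + dc * dc <= radius * radius]
    out = np.empty_like(image, dtype=float)
    for r in range(rows):
        for c in range(cols):
            acc = 0.0
            for dr, dc in offsets:
                rr = min(max(r + dr, 0), rows - 1)
                cc = min(max(c + dc, 0), cols - 1)
                acc += image[rr, cc]
            out[r, c] = acc / len(offsets)
    return out


def isodata_fixed_point_oracle(image: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive scan for the histogram threshold satisfying the
    mean-of-means fixed point t = (mu_below + mu_above) / 2."""
    hist, edges = np.histogram(image.ravel(), bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_err = None, np.inf
    for cut in range(1, n_bins):
        w_lo, w_hi = hist[:cut].sum(), hist[cut:].sum()
        if w_lo == 0 or w_hi == 0:
            continue
        mu_lo = (hist[:cut] * centers[:cut]).sum() / w_lo
        mu_hi = (hist[cut:] * centers[cut:]).sum() / w_hi
        t = 0.5 * (mu_lo + mu_hi)
        err = abs(t - edges[cut])
        if err < best_err:
            best_err, best_t = err, t
    return best_t


def flood_fill_label_oracle(mask: np.ndarray, min_area: int,
                            exclude_edges: bool) -> np.ndarray:
    """Hole-filling + 8-connected labeling + filters, written from scratch
    with BFS flood fills (4-connected background reach for holes)."""
    rows, cols = mask.shape
    mask = mask.astype(bool).copy()
    # fill holes: background not reachable from the border (4-connected)
    reach = np.zeros_like(mask)
    stack = [(r, c) for r in range(rows) for c in (0, cols - 1) if not mask[r, c]]
    stack += [(r, c) for c in range(cols) for r in (0, rows - 1) if not mask[r, c]]
    for r, c in stack:
        reach[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                stack.append((rr, cc))
    mask |= ~reach
    # 8-connected components in raster order of first pixel
    labels = np.zeros(mask.shape, dtype=int)
    components = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                comp = [(r, c)]
                labels[r, c] = -1
                queue = [(r, c)]
                while queue:
                    qr, qc = queue.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = qr + dr, qc + dc
                            if (0 <= rr < rows and 0 <= cc < cols
                                    and mask[rr, cc] and labels[rr, cc] == 0):
                                labels[rr, cc] = -1
                                comp.append((rr, cc))
                                queue.append((rr, cc))
                components.append(comp)
    out = np.zeros(mask.shape, dtype=int)
    next_id = 1
    for comp in components:
        if len(comp) < min_area:
            continue
        touches = any(r in (0, rows - 1) or c in (0, cols - 1) for r, c in comp)
        if exclude_edges and touches:
            continue
        for r, c in comp:
            out[r, c] = next_id
        next_id += 1
    return out


# ---------------------------------------------------------------------------
# projections

class TestProjections:
    def test_baseline_of_constant_movie(self, constant_movie):
        assert np.all(baseline_projection(constant_movie, 5) == 7.0)

    def test_baseline_of_alternating_frames(self):
        frames = np.zeros((12, 8, 8))
        frames[1::2] = 2.0
        movie = make_movie(frames)
        assert np.allclose(baseline_projection(movie, 10), 1.0)

    def test_baseline_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(0)
        movie = make_movie(rng.uniform(0, 50, (30, 12, 12)))
        oracle = sum(movie.frames[t] for t in range(20)) / 20.0
        assert np.allclose(baseline_projection(movie, 20), oracle, atol=1e-6)

    def test_baseline_count_out_of_range(self, constant_movie):
        with pytest.raises(ValueError):
            baseline_projection(constant_movie, 0)
        with pytest.raises(ValueError):
            baseline_projection(constant_movie, 20)

    def test_baseline_overlapping_stimulus_warns(self):
        movie = make_movie(np.ones((20, 8, 8)), stim=100.0)
        with pytest.warns(UserWarning, match="stimulus"):
            baseline_projection(movie, 15)

    def test_response_of_constant_movie_is_zero(self, constant_movie):
        assert np.all(response_image(constant_movie, 5) == 0.0)

    def test_response_recovers_injected_spot(self):
        frames = np.full((100, 16, 16), 10.0)
        frames[60, 5, 5] += 3.5
        movie = make_movie(frames)
        resp = response_image(movie, 45)
        assert resp[5, 5] == pytest.approx(3.5)
        resp[5, 5] = 0.0
        assert np.all(resp == 0.0)

    def test_response_at_centers_vs_rendering_oracle(self):
        cfg = SimConfig(image_shape=(96, 96), n_boutons=12, release_probability=1.0,
                        spontaneous_rate_per_bouton_per_min=0.0, noise_sd=0.0, seed=6)
        movie, events = simulate_evoked_movie(cfg)
        resp = response_image(movie, 45)
        # oracle: dense-grid kernel averaged over each exposure window
        grid = np.arange(0.0, 1500.0, 0.01)
        kern = (1 - np.exp(-np.clip(grid, 0, None) / cfg.transient_rise_ms)) * np.exp(
            -np.clip(grid, 0, None) / cfg.transient_decay_ms)
        kern /= kern.max()
        for ev in events.itertuples():
            rel = grid - (ev.event_time_ms - 0.0)
            k = np.where(rel >= 0, np.interp(np.clip(rel, 0, None), grid, kern), 0.0)
            frame_means = k[: 150 * 1000].reshape(150, 1000).mean(axis=1)
            injected_peak = cfg.transient_amplitude_dff * cfg.baseline_intensity * (
                frame_means.max())
            assert resp[int(ev.center_row), int(ev.center_col)] >= 0.8 * injected_peak


# ---------------------------------------------------------------------------
# band-pass

class TestBandpass:
    def test_constant_image_maps_to_zero(self):
        assert np.allclose(bandpass(np.full((32, 32), 9.0)), 0.0)

    def test_single_bright_pixel_neighborhood_count(self):
        img = np.zeros((64, 64))
        img[32, 32] = 100.0
        n_disk = int(np.sum([
            1 for dr in range(-10, 11) for dc in range(-10, 11)
            if dr * dr + dc * dc <= 100
        ]))
        out = bandpass(img, radius_px=10)
        assert out[32, 32] == pytest.approx(100.0 * (1 - 1 / n_disk), rel=1e-9)

    def test_matches_direct_neighborhood_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, (24, 24))
        out = bandpass(img, radius_px=5)
        assert np.allclose(out, img - mean_filter_oracle(img, 5), atol=1e-6)

    def test_radius_too_large_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((16, 16)), radius_px=9)


# ---------------------------------------------------------------------------
# thresholding

class TestThreshold:
    def test_bimodal_isodata_matches_fixed_point_oracle(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(10, 1, 5000), rng.normal(100, 5, 5000)])
        img = img.reshape(100, 100)
        res = threshold_auto(img, method="isodata")
        assert 10 < res.threshold < 100
        oracle = isodata_fixed_point_oracle(img)
        bin_width = np.ptp(img) / 256
        assert res.threshold == pytest.approx(oracle, abs=2 * bin_width)

    def test_manual_threshold(self):
        img = np.array([[40.0, 60.0]])
        res = threshold_auto(img, method="manual", manual_value=50.0)
        assert res.mask.tolist() == [[False, True]]

    def test_mask_size_monotone_in_manual_value(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (32, 32))
        counts = [threshold_auto(img, "manual", manual_value=v).mask.sum()
                  for v in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_image_requires_manual(self):
        with pytest.raises(ValueError, match="manual"):
            threshold_auto(np.ones((8, 8)))


# ---------------------------------------------------------------------------
# watershed + labeling

def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


class TestWatershed:
    def test_single_disc_unchanged(self):
        mask = disc_mask((32, 32), (16, 16), 7)
        assert np.array_equal(watershed_split(mask), mask)

    def test_two_overlapping_discs_split(self):
        mask = disc_mask((40, 40), (20, 15), 6) | disc_mask((40, 40), (20, 25), 6)
        n_before = ndi.label(mask, structure=EIGHT_CONNECTED)[1]
        split = watershed_split(mask)
        n_after = ndi.label(split, structure=EIGHT_CONNECTED)[1]
        assert n_before == 1
        assert n_after == 2
        # EDT oracle: number of separated regional-maximum clusters
        from skimage.morphology import local_maxima
        dist = ndi.distance_transform_edt(mask)
        n_maxima = ndi.label(local_maxima(dist, connectivity=2),
                             structure=EIGHT_CONNECTED)[1]
        assert n_after == n_maxima

    def test_component_count_never_decreases(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mask = ndi.binary_dilation(rng.uniform(size=(48, 48)) < 0.08,
                                       iterations=2)
            before = ndi.label(mask, structure=EIGHT_CONNECTED)[1]
            after = ndi.label(watershed_split(mask), structure=EIGHT_CONNECTED)[1]
            assert after >= before

    def test_empty_mask_passes_through(self):
        assert not watershed_split(np.zeros((8, 8), bool)).any()


class TestLabelRois:
    def test_two_blobs_away_from_edges(self):
        mask = np.zeros((32, 32), bool)
        mask[5:8, 5:9] = True      # 12 px
        mask[20:23, 20:24] = True  # 12 px
        rs = label_rois(mask)
        assert len(rs) == 2
        assert rs.rois.area_px.tolist() == [12, 12]

    def test_size_cut_is_at_least_10(self):
        mask = np.zeros((32, 32), bool)
        mask[5:8, 5:8] = True      # 9 px: dropped
        mask[20:22, 20:25] = True  # 10 px: kept
        rs = label_rois(mask, min_area_px=10)
        assert len(rs) == 1
        assert rs.rois.area_px.iloc[0] == 10

    def test_edge_touching_blob_removed(self):
        mask = np.zeros((32, 32), bool)
        mask[0:5, 10:16] = True    # 30 px on the top border
        assert len(label_rois(mask)) == 0
        assert len(label_rois(mask, exclude_edges=False)) == 1

    def test_holes_are_filled(self):
        mask = np.zeros((16, 16), bool)
        mask[4:10, 4:10] = True
        mask[6:8, 6:8] = False
        rs = label_rois(mask)
        assert rs.rois.area_px.iloc[0] == 36

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for p, min_area, exclude in [(0.35, 10, True), (0.5, 5, True),
                                     (0.45, 10, False), (0.6, 1, True)]:
            mask = rng.uniform(size=(48, 48)) < p
            got = label_rois(mask, min_area_px=min_area, exclude_edges=exclude)
            oracle = flood_fill_label_oracle(mask, min_area, exclude)
            assert np.array_equal(got.label_image, oracle)


# ---------------------------------------------------------------------------
# end-to-end chain

class TestDetectRois:
    def test_precision_and_recall_on_default_conditions(self):
        cfg = SimConfig(seed=21)
        movie, events = simulate_evoked_movie(cfg)
        roiset, log = detect_rois(movie)
        releasing = events.loc[events.latency_class != "spontaneous",
                               ["center_row", "center_col"]].drop_duplicates().to_numpy()
        m = match_rois_to_boutons(roiset, releasing)
        assert m["precision"] >= 0.9
        assert m["recall"] >= 0.9
        assert log["threshold_value"] >= log["threshold_auto_value"]

    def test_pure_noise_movie_yields_almost_no_rois(self):
        cfg = SimConfig(seed=22)
        signal_movie, _ = simulate_evoked_movie(cfg)
        n_signal = len(detect_rois(signal_movie)[0])
        noise_cfg = SimConfig(seed=22, release_probability=0.0,
                              spontaneous_rate_per_bouton_per_min=0.0)
        noise_movie, _ = simulate_evoked_movie(noise_cfg)
        n_noise = len(detect_rois(noise_movie)[0])
        assert n_noise <= 0.02 * n_signal

    def test_manual_method_bypasses_noise_floor(self):
        frames = np.full((60, 32, 32), 10.0)
        frames[30, 10:14, 10:14] += 50.0
        movie = make_movie(frames, stim=250.0)
        roiset, log = detect_rois(movie, baseline_frame_count=20,
                                  bandpass_radius_px=8,
                                  threshold_method="manual", manual_threshold=20.0)
        assert log["threshold_value"] == 20.0
        assert len(roiset) == 1
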