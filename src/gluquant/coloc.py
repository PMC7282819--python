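"""Pearson colocalization with Costes automatic thresholding.

The Pearson correlation coefficient (PCC) between two fluorescence
channels is dominated by the many dim background pixels; the Costes
procedure removes that bias by finding, per channel, the intensity
threshold below which the two channels are uncorrelated.  Channel 2 is
regressed on channel 1 by orthogonal (total least squares) regression,
``ch2 ~ a*ch1 + b``; candidate thresholds T on channel 1 are scanned
downward from its maximum, and the Costes threshold is the largest T
for which the PCC restricted to pixels with ``ch1 < T`` and
``ch2 < a*T + b`` is <= 0.  The reported colocalization PCC is then
computed over pixels above threshold in *either* channel (an
"and" variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColocResult",
    "pearson",
    "costes_threshold",
    "pcc_costes",
    "sample_rectangles",
    "pcc_costes_regions",
]


@dataclass
class ColocResult:
    pcc_global: float
    costes_thresholds: tuple[float, float]
    pcc_above_threshold: float
    n_pixels_used: int
    reliable: bool


def pearson(ch1: np.ndarray, ch2: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Product-moment correlation over (masked) pixels."""
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ch1.shape:
            raise ValueError("mask must match the channel shape")
        a, b = ch1[mask], ch2[mask]
    else:
        a, b = ch1.ravel(), ch2.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("a channel is constant within the mask; PCC undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a*x + b via the principal axis."""
    cov = np.cov(np.vstack([x, y]))
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[0] == 0:
        raise ValueError("orthogonal regression is vertical; channels degenerate")
    a = v[1] / v[0]
    b = float(y.mean() - a * x.mean())
    return float(a), b


def costes_threshold(ch1: np.ndarray, ch2: np.ndarray,
                     n_levels: int = 256) -> tuple[float, float]:
    """Costes automatic threshold pair for two channels.

    Scans ``n_levels`` candidate thresholds on channel 1 downward from
    its maximum and returns the largest (T, a*T + b) whose
    below-threshold PCC is <= 0.  If no candidate satisfies the
    criterion the thresholds fall back to the channel minima with a
    warning.
    """
    x = np.asarray(ch1, dtype=float).ravel()
    y = np.asarray(ch2, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("channels must have the same shape")
    a, b = _orthogonal_regression(x, y)
    bright = x >= np.percentile(x, 75)
    if np.ptp(x[bright]) > 0 and np.ptp(y[bright]) > 0:
        r_bright = np.corrcoef(x[bright], y[bright])[0, 1]
        if r_bright ** 2 < 0.1:
            warnings.warn(
                "channels are nearly uncorrelated in their bright range; "
                "the Costes threshold may be meaningless"
            )
    levels = np.unique(x)
    if levels.size > n_levels:
        levels = np.linspace(x.min(), x.max(), n_levels)
    for t1 in levels[::-1]:
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        if below.sum() < 2:
            continue
        xb, yb = x[below], y[below]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        if np.corrcoef(xb, yb)[0, 1] <= 0:
            return float(t1), float(t2)
    warnings.warn(
        "no threshold gives non-positive below-threshold PCC; "
        "falling back to the channel minima"
    )
    return float(x.min()), float(y.min())


def pcc_costes(ch1: np.ndarray, ch2: np.ndarray,
               mode: str = "either") -> ColocResult:
    """Global and Costes-thresholded PCC for a channel pair.

    ``mode='either'`` (default) computes the thresholded PCC over
    pixels above threshold in either channel; ``mode='both'`` requires
    both.  Results with fewer than 10 usable pixels are flagged
    unreliable.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    pcc_global = pearson(ch1, ch2)
    t1, t2 = costes_threshold(ch1, ch2)
    if mode == "either":
        above = (ch1 >= t1) | (ch2 >= t2)
    elif mode == "both":
        above = (ch1 >= t1) & (ch2 >= t2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_used = int(above.sum())
    reliable = n_used >= 10
    if n_used >= 2 and np.ptp(ch1[above]) > 0 and np.ptp(ch2[above]) > 0:
        pcc_above = pearson(ch1, ch2, mask=above)
    else:
        pcc_above = float("nan")
        reliable = False
    if not reliable:
        warnings.warn(f"only {n_used} pixels above threshold; result unreliable")
    return ColocResult(
        pcc_global=pcc_global, costes_thresholds=(t1, t2),
        pcc_above_threshold=pcc_above, n_pixels_used=n_used, reliable=reliable,
    )


def sample_rectangles(image_shape: tuple[int, int], n_rects: int,
                      rect_shape: tuple[int, int], seed: int = 0) -> list[tuple]:
    """Seeded random rectangles (row0, col0, height, width) inside the image."""
    rows, cols = image_shape
    h, w = rect_shape
    if h > rows or w > cols:
        raise ValueError("rectangle larger than the image")
    rng = np.random.default_rng(seed)
    return [
        (int(rng.integers(0, rows - h + 1)), int(rng.integers(0, cols - w + 1)), h, w)
        for _ in range(n_rects)
    ]


def pcc_costes_regions(ch1: np.ndarray, ch2: np.ndarray,
                       rects: list[tuple] | None = None, n_rects: int = 5,
                       rect_shape: tuple[int, int] | None = None,
                       seed: int = 0, mode: str = "either") -> pd.DataFrame:
    """Per-rectangle Costes-thresholded PCC plus a pooled full-frame row.

    ``rects`` is a list of (row0, col0, height, width); when omitted,
    ``n_rects`` rectangles of ``rect_shape`` (default: half the image)
    are sampled with the given seed.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if rects is None:
        if rect_shape is None:
            rect_shape = (ch1.shape[0] // 2, ch1.shape[1] // 2)
        rects = sample_rectangles(ch1.shape, n_rects, rect_shape, seed=seed)
    records = []
    for i, (r0, c0, h, w) in enumerate(rects):
        sub = pcc_costes(ch1[r0:r0 + h, c0:c0 + w], ch2[r0:r0 + h, c0:c0 + w], mode=mode)
        records.append({
            "region": i, "row0": r0, "col0": c0, "height": h, "width": w,
            "pcc_global": sub.pcc_global,
            "pcc_above_threshold": sub.pcc_above_threshold,
            "n_pixels_used": sub.n_pixels_used, "reliable": sub.reliable,
        })
    pooled = pcc_costes(ch1, ch2, mode=mode)
    records.append({
        "region": "pooled", "row0": 0, "col0": 0,
        "height": ch1.shape[0], "width": ch1.shape[1],
        "pcc_global": pooled.pcc_global,
        "pcc_above_threshold": pooled.pcc_above_threshold,
        "n_pixels_used": pooled.n_pixels_used, "reliable": pooled.reliable,
    })
    return pd.DataFrame.from_records(records)
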