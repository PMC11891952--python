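"""256-bin histograms and the three auto-threshold algorithms.

The pipeline selects between three classical histogram-shape thresholders,
each suited to a different signal morphology:

* ``threshold_default`` — iterative intermeans (the IsoData family), for
  green-dominant control images with a clear bimodal histogram;
* ``threshold_otsu`` — maximum between-class variance, for treated-sample
  green channels where the foreground class has shrunk;
* ``threshold_triangle`` — Zack's geometric method, for the red channel in
  both conditions, whose histogram is a background peak with a long dim
  tail of punctate signal.

All three operate on a 256-bin histogram and return a *bin index*; 16-bit
planes are min-max scaled into the 256 bins and the chosen bin is mapped
back to source intensity units.  Foreground polarity is bright-on-dark:
pixels strictly above the threshold are foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram256",
    "histogram256",
    "threshold_otsu",
    "threshold_default",
    "threshold_triangle",
    "apply_threshold",
]


@dataclass(frozen=True)
class Histogram256:
    """A 256-bin intensity histogram with its mapping back to intensities.

    ``counts[i]`` is the number of pixels in bin ``i``; ``bin_to_intensity``
    recovers the source-intensity value of a bin centre (identity for 8-bit
    input, inverse of the min-max scaling for 16-bit input).
    """

    counts: np.ndarray
    source_bit_depth: int
    intensity_min: float
    bin_scale: float  # intensity units per bin

    def bin_to_intensity(self, t: int) -> float:
        return self.intensity_min + t * self.bin_scale

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def histogram256(img: np.ndarray) -> Histogram256:
    """Build the 256-bin histogram of a grayscale plane.

    8-bit planes bin intensities directly; higher-depth planes are scaled
    linearly from [min, max] into bins 0..255 (a constant plane occupies a
    single bin).
    """
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        counts = np.bincount(arr.ravel(), minlength=256)[:256]
        return Histogram256(counts=counts, source_bit_depth=8,
                            intensity_min=0.0, bin_scale=1.0)
    f = arr.astype(float)
    lo = float(f.min())
    hi = float(f.max())
    if hi == lo:
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = f.size
        return Histogram256(counts=counts, source_bit_depth=16,
                            intensity_min=lo, bin_scale=1.0)
    scale = (hi - lo) / 255.0
    bins = np.clip(np.round((f - lo) / scale).astype(int), 0, 255)
    counts = np.bincount(bins.ravel(), minlength=256)[:256]
    return Histogram256(counts=counts, source_bit_depth=16,
                        intensity_min=lo, bin_scale=scale)


def _occupied(h: Histogram256) -> np.ndarray:
    return np.nonzero(h.counts)[0]


def threshold_otsu(h: Histogram256) -> int:
    """Otsu's threshold: the cut maximising between-class variance.

    Classes are bins [0..t] and (t..255].  Ties break to the lowest
    qualifying index; a single-bin histogram returns that bin.
    """
    counts = h.counts.astype(float)
    occ = _occupied(h)
    if occ.size == 0:
        raise ValueError("empty histogram")
    if occ.size == 1:
        return int(occ[0])
    bins = np.arange(256, dtype=float)
    w0 = np.cumsum(counts)                      # mass of [0..t]
    m0 = np.cumsum(counts * bins)               # first moment of [0..t]
    total = w0[-1]
    mu_total = m0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        between = w0 * w1 * (mean0 - mean1) ** 2
    between[~np.isfinite(between)] = -np.inf
    between = between[:255]                     # cut after bin t, t in 0..254
    return int(np.argmax(between))              # argmax takes the first max


def threshold_default(h: Histogram256) -> int:
    """Iterative intermeans ("IsoData" family) threshold.

    Starting from the histogram midpoint, repeatedly set
    ``t = round((mean of bins <= t + mean of bins > t) / 2)``
    (round half up) until the value is stable.
    """
    counts = h.counts.astype(float)
    occ = _occupied(h)
    if occ.size == 0:
        raise ValueError("empty histogram")
    if occ.size == 1:
        return int(occ[0])
    bins = np.arange(256, dtype=float)
    t = 127
    for _ in range(256):
        low = counts[: t + 1]
        high = counts[t + 1:]
        if low.sum() == 0:
            mean_low = 0.0
        else:
            mean_low = float((low * bins[: t + 1]).sum() / low.sum())
        if high.sum() == 0:
            mean_high = mean_low
        else:
            mean_high = float((high * bins[t + 1:]).sum() / high.sum())
        t_new = int(np.floor((mean_low + mean_high) / 2.0 + 0.5))
        if t_new == t:
            return t
        t = t_new
    return t


def threshold_triangle(h: Histogram256) -> int:
    """Zack's triangle threshold.

    A line is drawn from the histogram peak to the furthest non-empty tail
    bin; the threshold is the bin maximising perpendicular distance from
    the histogram profile to that line.  If the long tail lies left of the
    peak the histogram is mirrored, thresholded, and the result mirrored
    back.  A flat histogram returns its lowest occupied bin.
    """
    counts = h.counts.astype(float)
    occ = _occupied(h)
    if occ.size == 0:
        raise ValueError("empty histogram")
    if occ.size == 1:
        return int(occ[0])
    first, last = int(occ[0]), int(occ[-1])
    peak = int(np.argmax(counts))
    if np.all(counts[occ] == counts[peak]):  # flat: no triangle to draw
        return first
    # mirror so the long tail is on the right of the peak
    mirrored = (peak - first) >= (last - peak)
    if mirrored:
        counts = counts[::-1]
        peak = 255 - peak
        last = 255 - first
    # line from (peak, counts[peak]) to (last, counts[last]); for every bin
    # between them the perpendicular distance below the line is
    # proportional to dx*(counts[peak]-counts[x]) - dy*(x-peak), which
    # vanishes at both endpoints
    dx = last - peak
    dy = counts[peak] - counts[last]
    xs = np.arange(peak, last + 1)
    dist = dx * (counts[peak] - counts[xs]) - dy * (xs - peak)
    t = int(xs[np.argmax(dist)])
    if mirrored:
        t = 255 - t
    return t


def apply_threshold(img: np.ndarray, t: float) -> np.ndarray:
    """Binarise: pixels with intensity strictly above ``t`` are foreground."""
    return np.asarray(img) > t
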