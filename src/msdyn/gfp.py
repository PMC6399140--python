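"""Global field power: re-referencing, band-pass filtering, GFP computation,
Gaussian smoothing, peak detection and peak subsampling.

GFP(t) is the spatial standard deviation of the average-referenced scalp map
at sample t (population convention, divide by the channel count).  Its local
maxima are the moments of highest topographic signal-to-noise and are the
only samples fed to template clustering.
"""
from __future__ import annotations

import numpy as np
from mne.filter import filter_data
from scipy.ndimage import convolve1d

from .datatypes import (
    EEGRecording,
    GFPSeries,
    InvalidConfigError,
    InvalidInputError,
    PeakSet,
)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous channel mean from every sample.

    Idempotent; afterwards each column of the data matrix sums to zero.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.sampling_rate, list(rec.channel_labels),
                        rec.subject_id)


def bandpass(rec: EEGRecording, low: float = 2.0, high: float = 20.0
             ) -> EEGRecording:
    """Zero-phase FIR band-pass (default 2-20 Hz).

    Uses a windowed-FIR design with heuristically chosen transition bands
    applied forward with group-delay compensation, so a band-limited input
    comes out with no phase shift.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise InvalidConfigError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq}")
    data = filter_data(rec.data, rec.sampling_rate, low, high,
                       method="fir", phase="zero", verbose=False)
    return EEGRecording(data, rec.sampling_rate, list(rec.channel_labels),
                        rec.subject_id)


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Spatial standard deviation per sample (average reference enforced)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(data ** 2, axis=0))
    return GFPSeries(values, rec.sampling_rate, smoothed=False)


def gaussian_kernel(window: int, sigma: float = 1.0) -> np.ndarray:
    """Normalized Gaussian taps on integer offsets -(w//2)..w//2."""
    if window < 1 or window % 2 == 0:
        raise InvalidConfigError("window must be odd and >= 1")
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_gfp(gfp: GFPSeries, window: int = 5, sigma: float = 1.0
               ) -> GFPSeries:
    """Gaussian-weighted moving average (default 5 taps, sigma = 1 sample).

    Edges are handled by reflection, so a constant series is unchanged.
    """
    kernel = gaussian_kernel(window, sigma)
    values = convolve1d(gfp.values, kernel, mode="reflect")
    return GFPSeries(values, gfp.sampling_rate, smoothed=True)


def find_gfp_peaks(gfp: GFPSeries) -> PeakSet:
    """Interior local maxima of the (smoothed) GFP series.

    A sample t is a peak when g(t-1) < g(t) >= g(t+1): plateaus contribute
    their first sample, endpoints never qualify.
    """
    g = gfp.values
    if g.size < 3:
        raise InvalidInputError("need at least 3 samples to find peaks")
    interior = np.arange(1, g.size - 1)
    mask = (g[interior - 1] < g[interior]) & (g[interior] >= g[interior + 1])
    return PeakSet(interior[mask])


def subsample_peaks(peaks: PeakSet, max_n: int = 10_000,
                    seed: int | None = 0) -> PeakSet:
    """Uniform subsample without replacement to at most ``max_n`` peaks,
    returned in ascending order; all peaks kept when there are fewer."""
    if peaks.n_selected <= max_n:
        return PeakSet(peaks.indices, n_total=peaks.n_total, seed=seed)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(peaks.indices, size=max_n, replace=False)
    return PeakSet(np.sort(chosen), n_total=peaks.n_total, seed=seed)


def peak_maps(rec: EEGRecording, peaks: PeakSet
              ) -> tuple[np.ndarray, np.ndarray]:
    """Extract (maps, gfp_at_peaks) at peak indices from a recording.

    Maps are taken from the band-passed but unsmoothed data (smoothing is
    only used to localize peaks), average-referenced.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    maps = data[:, peaks.indices].T
    g = np.sqrt(np.mean(maps ** 2, axis=1))
    return maps, g
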