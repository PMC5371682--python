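"""Spectral period estimation and cross-frequency-coupling metrics.

Time is a dimensionless map-iteration count, so oscillation speed is
expressed as a *period in time steps*: a time course is reduced to its
power spectrum over a fixed window (default 4096 samples) and the
lowest-frequency qualifying spectral peak is translated into
``period = window / bin``.

The coupled network produces a slow oscillation in the excitatory
population and a fast one in the inhibitory population.
Phase-amplitude cross-frequency coupling (CFC) is quantified the direct
way: detect individual fast-oscillation peaks, measure each peak's
amplitude (peak minus preceding trough) and local period, and bin them
by the phase of the slow oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert

__all__ = [
    "PeriodEstimate", "CFCProfile", "dominant_period", "slow_phase",
    "cfc_profile", "items_per_slow_cycle",
]

DEFAULT_WINDOW = 4096


class SpectralError(ValueError):
    """Raised when a series lacks the spectral structure an analysis needs."""


@dataclass
class PeriodEstimate:
    """Period (time steps) from the first qualifying spectral peak."""

    period: float | None
    bin: int | None
    window: int
    power: np.ndarray = field(repr=False)
    no_peak: bool = False


def _qualifying_peak_bins(power: np.ndarray, threshold: float) -> np.ndarray:
    """Indices (>=1, DC excluded) of local maxima above the relative cut."""
    n = len(power)
    if n < 3:
        return np.array([], dtype=int)
    body = power[1:]            # DC excluded
    if body.max() <= 0:
        return np.array([], dtype=int)
    cut = threshold * body.max()
    peaks = []
    for k in range(1, n - 1):
        left = power[k - 1] if k > 1 else 0.0   # bin 1 may lead the spectrum
        if power[k] > left and power[k] >= power[k + 1] and power[k] >= cut:
            peaks.append(k)
    return np.array(peaks, dtype=int)


def dominant_period(series, *, window: int = DEFAULT_WINDOW,
                    threshold: float = 0.05,
                    prefer: str = "lowest") -> PeriodEstimate:
    """Oscillation period from the first typical peak of the periodogram.

    The first ``window`` samples are mean-detrended and transformed with
    a rectangular window; among local spectral maxima whose power
    reaches ``threshold`` times the spectral maximum (DC excluded), the
    lowest-frequency one is selected (``prefer='largest'`` selects the
    global maximum instead).  A constant series, or one with no
    qualifying peak, returns a flagged no-peak estimate.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(series) < window:
        raise ValueError(f"series shorter than the {window}-sample window")
    x = series[:window]
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    peaks = _qualifying_peak_bins(spec, threshold)
    if len(peaks) == 0:
        return PeriodEstimate(None, None, window, spec, no_peak=True)
    k = int(peaks[0]) if prefer == "lowest" else int(peaks[np.argmax(spec[peaks])])
    return PeriodEstimate(window / k, k, window, spec)


def slow_phase(series, *, window: int | None = None,
               min_period: float = 20.0, band: float = 0.5) -> np.ndarray:
    """Instantaneous phase of the slow oscillatory component, in [0, 2pi).

    The slow spectral peak (period above ``min_period``; for a pure tone
    the only peak) is located on the full series length, the series is
    band-passed to ``(1 +/- band)`` times that frequency by spectral
    masking, and the phase is the angle of the analytic signal.  The
    phase advances 2pi per slow period on average.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    window = n if window is None else window
    est = dominant_period(series, window=window)
    if est.no_peak:
        raise SpectralError("series has no qualifying spectral peak")
    period = est.period
    if period < min_period:
        # keep looking among qualifying peaks for a slow component
        peaks = _qualifying_peak_bins(est.power, 0.05)
        slow = [k for k in peaks if window / k >= min_period]
        if not slow and period < min_period:
            raise SpectralError(
                f"no slow spectral peak (period >= {min_period}) found")
        if slow:
            period = window / slow[0]
    f0 = 1.0 / period
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec = np.fft.rfft(series - series.mean())
    mask = (freqs >= (1.0 - band) * f0) & (freqs <= (1.0 + band) * f0)
    filtered = np.fft.irfft(spec * mask, n=n)
    return np.mod(np.angle(hilbert(filtered)), 2.0 * np.pi)


def _fast_peaks(fast: np.ndarray, prominence_frac: float = 0.01):
    """Indices, amplitudes and local periods of fast-oscillation peaks.

    Amplitude is peak height minus the preceding trough; the local
    period is the spacing to the previous peak.
    """
    rng = fast.max() - fast.min()
    if rng <= 0:
        return (np.array([], dtype=int),) * 3
    idx, _ = find_peaks(fast, prominence=prominence_frac * rng)
    amps = np.empty(len(idx))
    prev = 0
    for j, k in enumerate(idx):
        trough = fast[prev:k].min() if k > prev else fast[k]
        amps[j] = fast[k] - trough
        prev = k
    local_period = np.diff(idx, prepend=idx[0] if len(idx) else 0).astype(float)
    if len(idx):
        local_period[0] = np.nan  # no preceding peak
    return idx, amps, local_period


@dataclass
class CFCProfile:
    """Fast-oscillation amplitude/period binned by slow-oscillation phase."""

    bin_edges: np.ndarray
    amplitude: np.ndarray         # mean fast amplitude per phase bin (nan: empty)
    period: np.ndarray            # mean local fast period per phase bin
    counts: np.ndarray            # fast peaks per bin
    modulation_depth: float       # max - min of the per-bin amplitude
    mode: str                     # none / continuous / intermittent


def cfc_profile(slow, fast, n_bins: int = 18, *,
                depth_threshold: float = 0.1,
                suppression: float = 0.25,
                prominence_frac: float = 0.01) -> CFCProfile:
    """Phase-amplitude CFC profile of a fast series against a slow one.

    Fast peaks are detected as local maxima with a minimum prominence of
    ``prominence_frac`` of the series range; each peak contributes its
    amplitude and local period to the phase bin of the slow oscillation
    at the peak time.  The mode label is *none* when the modulation
    depth stays below ``depth_threshold`` of the maximum bin amplitude,
    *intermittent* when some bin is suppressed (empty, or below
    ``suppression`` of the maximum bin), and *continuous* otherwise.
    """
    slow = np.asarray(slow, dtype=float)
    fast = np.asarray(fast, dtype=float)
    if slow.shape != fast.shape:
        raise ValueError("slow and fast series must have equal length")
    idx, amps, local_period = _fast_peaks(fast, prominence_frac)
    if len(idx) < 10:
        raise SpectralError(
            f"only {len(idx)} fast peaks detected; need at least 10")
    phase = slow_phase(slow)[idx]
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    amplitude = np.full(n_bins, np.nan)
    period = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            amplitude[b] = amps[sel].mean()
            with np.errstate(invalid="ignore"):
                pb = local_period[sel]
                if np.any(np.isfinite(pb)):
                    period[b] = np.nanmean(pb)
    filled = amplitude[np.isfinite(amplitude)]
    depth = float(filled.max() - filled.min()) if len(filled) else 0.0
    peak_amp = float(filled.max()) if len(filled) else 0.0
    if peak_amp <= 0 or depth <= depth_threshold * peak_amp:
        mode = "none"
    elif np.any(counts == 0) or np.any(
            np.nan_to_num(amplitude, nan=0.0) < suppression * peak_amp):
        mode = "intermittent"
    else:
        mode = "continuous"
    return CFCProfile(edges, amplitude, period, counts, depth, mode)


def items_per_slow_cycle(fast, slow, *, min_cycles: int = 5,
                         prominence_frac: float = 0.01,
                         min_amplitude_frac: float = 0.25):
    """Mean number of non-suppressed fast peaks per slow cycle.

    Cycle boundaries are the wraps of the slow-oscillation phase; only
    complete cycles are counted.  In the intermittent-coupling state
    part of each slow cycle carries only residual ripple rather than
    full fast cycles, so a peak counts as an "item" only when its
    amplitude reaches ``min_amplitude_frac`` of the largest peak
    amplitude -- the same suppression threshold the CFC mode label
    uses.  Returns ``(mean, per_cycle_counts)``.
    """
    fast = np.asarray(fast, dtype=float)
    slow = np.asarray(slow, dtype=float)
    phase = slow_phase(slow)
    wraps = np.flatnonzero(np.diff(phase) < -np.pi)
    if len(wraps) < min_cycles + 1:
        raise SpectralError(
            f"need at least {min_cycles} complete slow cycles, "
            f"found {max(len(wraps) - 1, 0)}")
    idx, amps, _ = _fast_peaks(fast, prominence_frac)
    if len(idx):
        idx = idx[amps >= min_amplitude_frac * amps.max()]
    counts = np.array([
        np.count_nonzero((idx > wraps[i]) & (idx <= wraps[i + 1]))
        for i in range(len(wraps) - 1)], dtype=float)
    return float(counts.mean()), counts
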