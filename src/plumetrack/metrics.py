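"""Responsivity, mean response, and band-limited response power.

Responsivity asks a coarse question — did the glomerulus respond to the
plume at all? — by counting time points whose baseline-normalized activity
leaves the 95% band (|z| > 1.96, two-sided: suppression counts) during the
plume plus one second (rebound window), and flagging trials whose count
beats the chance expectation.  Response power asks how much of the response
lives in the stimulus band (0-5 Hz), comparing plume to baseline periods on
a per-second (density) scale so unequal window lengths are comparable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as ssig
from scipy import stats as sps

from .plume_stats import band_spectrum


def trial_events(z: np.ndarray, window: slice, threshold: float = 1.96) -> int:
    """Count suprathreshold time points (|z| > threshold) in the window."""
    z = np.asarray(z, dtype=float)
    seg = z[window]
    if seg.size == 0:
        raise ValueError("response window falls outside the trial")
    return int(np.sum(np.abs(seg) > threshold))


def event_threshold(n_window_samples: int, null_rate: float = 0.05) -> int:
    """Chance-level event count: null_rate of window samples, rounded up."""
    return math.ceil(null_rate * n_window_samples)


def responsivity(
    event_counts: np.ndarray, n_window_samples: int, null_rate: float = 0.05
) -> float:
    """Proportion of trials with strictly more events than chance expects."""
    event_counts = np.asarray(event_counts)
    if event_counts.size == 0:
        raise ValueError("no trials")
    thresh = event_threshold(n_window_samples, null_rate)
    return float(np.mean(event_counts > thresh))


def mean_response(traces: np.ndarray, window: slice) -> float:
    """Mean standardized deconvolved response over the middle-8 s window,
    averaged across the trials supplied (one flow condition)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    return float(traces[:, window].mean())


def response_power_change(
    trace: np.ndarray,
    baseline: slice,
    plume: slice,
    fs: float,
    band: tuple[float, float] = (0.0, 5.0),
) -> tuple[float, float]:
    """Band-power change (plume minus baseline) and plume band fraction.

    The periodogram is Parseval-normalized (spectral sum = window variance),
    which makes band power intensive — independent of window length for
    stationary signals — so the 5 s baseline and the longer plume window are
    directly comparable.  Returns (delta_band_power,
    band_fraction_during_plume).
    """
    trace = np.asarray(trace, dtype=float)
    if band[1] > fs / 2:
        raise ValueError("band extends above Nyquist")
    out = []
    for window in (baseline, plume):
        seg = trace[window]
        if seg.size < 2 * fs:
            raise ValueError("power windows must span at least 2 s")
        spec = band_spectrum(seg, fs, band)
        out.append((spec.band_power, spec.band_fraction))
    (base_power, _), (plume_power, plume_fraction) = out
    return plume_power - base_power, plume_fraction


def stft(
    trace: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectrum (Hann taper, PSD scaling).

    Returns (freqs, times, S) where each column is a one-sided power
    spectral density, so integrating a column over frequency recovers that
    segment's power (windowed Parseval) — used to visualize how response
    power concentrates below 5 Hz across the trial.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(window_s * fs)
    if nperseg > trace.size:
        raise ValueError("STFT window longer than the trace")
    freqs, times, S = ssig.spectrogram(
        trace,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return freqs, times, S


def percentile_subset_contrast(
    mean_responses: np.ndarray,
    power_low: np.ndarray,
    power_high: np.ndarray,
    percentile: float = 75.0,
) -> dict:
    """Paired high-vs-low power contrast within the strongest responders.

    The subset is glomeruli whose overall mean response is at or above the
    given percentile of the population.  ``percentile=0`` reproduces the
    whole-population comparison.
    """
    mean_responses = np.asarray(mean_responses, dtype=float)
    power_low = np.asarray(power_low, dtype=float)
    power_high = np.asarray(power_high, dtype=float)
    if mean_responses.size < 8:
        raise ValueError("need at least 8 glomeruli for a percentile subset")
    cut = np.percentile(mean_responses, percentile)
    subset = np.nonzero(mean_responses >= cut)[0]
    if subset.size < 2:
        raise ValueError("percentile subset smaller than 2 glomeruli")
    hi, lo = power_high[subset], power_low[subset]
    if np.allclose(hi, lo):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(hi, lo)
    return {
        "subset": subset,
        "n": int(subset.size),
        "mean_delta": float(np.mean(hi - lo)),
        "t": float(t),
        "p": float(p),
    }
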