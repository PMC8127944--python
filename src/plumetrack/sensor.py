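"""Metal-oxide (MOX) odor-sensor signal path.

A MOX ethanol sensor reports odor concentration through slow first-order
adsorption/desorption kinetics.  The fast concentration signal is recovered
by dividing the sensor spectrum by the spectrum of a double-exponential
response kernel.  The module covers the full path: Kaiser low-pass filter,
per-trial normalization, kernel construction, Fourier-domain deconvolution,
kernel calibration against a paired fast-reference (PID-like) recording, and
frame-averaged downsampling onto the imaging clock.

All traces are 1-D float arrays sampled at ``fs`` Hz spanning one trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class DegenerateTrialError(ValueError):
    """Raised when a trial has zero variance in its normalization window."""


# ---------------------------------------------------------------------------
# kernel


@dataclass(frozen=True)
class DeconvKernel:
    """Double-exponential sensor response kernel, integral-normalized.

    k0(t) = exp(-t/tau_decay) - exp(-t/tau_rise) on the trial-length grid,
    and k = k0 / integral(k0) so that the discrete integral (sum * dt) is 1.
    """

    tau_rise: float
    tau_decay: float
    fs: float
    values: np.ndarray = field(repr=False)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def __len__(self) -> int:
        return len(self.values)


#: Kernel time constants (s) for the Figaro TGS 2620 ethanol sensor,
#: obtained from a paired PID calibration recording.
DEFAULT_TAU_DECAY = 0.4629
DEFAULT_TAU_RISE = 0.0001


def build_kernel(
    tau_rise: float,
    tau_decay: float,
    fs: float,
    n_samples: int,
) -> DeconvKernel:
    """Build the integral-normalized double-exponential kernel.

    Parameters
    ----------
    tau_rise, tau_decay
        Time constants in seconds; requires ``tau_decay > tau_rise > 0``.
    fs
        Sampling rate in Hz.
    n_samples
        Trial length in samples; the kernel is evaluated on the same grid
        used for the trial-length Fourier transforms.
    """
    if not (tau_decay > tau_rise > 0):
        raise ValueError(
            f"require tau_decay > tau_rise > 0, got {tau_decay=}, {tau_rise=}"
        )
    if n_samples < 2:
        raise ValueError("kernel needs at least 2 samples")
    t = np.arange(n_samples) / fs
    k0 = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    integral = k0.sum() / fs
    if integral <= 0:
        raise ValueError("kernel integral is non-positive; check time constants")
    return DeconvKernel(tau_rise=tau_rise, tau_decay=tau_decay, fs=fs, values=k0 / integral)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form argmax of the un-normalized double exponential."""
    return np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)


# ---------------------------------------------------------------------------
# filtering and normalization


def kaiser_lowpass(
    x: np.ndarray,
    fs: float,
    cutoff: float = 30.0,
    numtaps: int = 101,
    beta: float = 5.0,
) -> np.ndarray:
    """Zero-phase Kaiser-window FIR low-pass.

    The linear-phase FIR is applied in a single pass with its group delay
    compensated (odd-length symmetric taps, 'same'-mode convolution on a
    reflect-padded signal), so the output is delay-free.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    taps = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    half = numtaps // 2
    xp = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    return np.convolve(xp, taps, mode="valid")


def kaiser_design_metadata(
    fs: float,
    cutoff: float = 30.0,
    numtaps: int = 101,
    beta: float = 5.0,
) -> dict:
    """Measured passband ripple and stopband attenuation of the design."""
    taps = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    w, h = signal.freqz(taps, worN=4096, fs=fs)
    mag = np.abs(h)
    passband = mag[w <= 0.8 * cutoff]
    stopband = mag[w >= cutoff + 0.25 * (fs / 2 - cutoff)]
    return {
        "numtaps": numtaps,
        "beta": beta,
        "cutoff_hz": cutoff,
        "fs_hz": fs,
        "passband_ripple_db": float(20 * np.log10(passband.max() / passband.min())),
        "stopband_attenuation_db": float(-20 * np.log10(stopband.max())),
    }


def normalize_trial(x: np.ndarray, window: slice) -> np.ndarray:
    """Z-score the whole trial by mean/SD taken over ``window``.

    The window is the plume-presentation span; normalization makes traces
    from different trials and gains comparable while preserving dynamics.
    """
    x = np.asarray(x, dtype=float)
    seg = x[window]
    if seg.size < 2:
        raise ValueError("normalization window needs at least 2 samples")
    sd = seg.std()
    if sd == 0:
        raise DegenerateTrialError("zero standard deviation in normalization window")
    return (x - seg.mean()) / sd


# ---------------------------------------------------------------------------
# Fourier deconvolution


def _kernel_spectrum(kernel: DeconvKernel, n: int) -> np.ndarray:
    if len(kernel) != n:
        raise ValueError(f"kernel length {len(kernel)} != trace length {n}")
    # dt factor approximates the continuous-time transform; it cancels in the
    # convolve -> deconvolve round trip but keeps DC gain at 1.
    return np.fft.rfft(kernel.values) * kernel.dt


def fourier_deconvolve(
    e: np.ndarray,
    kernel: DeconvKernel,
    eps: float = 1e-3,
    window: slice | None = None,
) -> np.ndarray:
    """Recover fast concentration dynamics: d = F^-1(e^ / k^).

    Frequency bins where |k^| < eps * max|k^| are zeroed rather than divided
    (spectral regularization; naive division amplifies noise without bound).
    The result is re-normalized over ``window`` (plume presentation) when
    given, otherwise over the whole trial.

    Note the deconvolution is known to produce an inflection artifact at
    plume onset; downstream analyses exclude the first and last second of
    the plume rather than correcting it here.
    """
    e = np.asarray(e, dtype=float)
    n = e.size
    K = _kernel_spectrum(kernel, n)
    mag = np.abs(K)
    if mag.max() == 0:
        raise ValueError("kernel spectrum is identically zero")
    ok = mag >= eps * mag.max()
    D = np.zeros_like(K)
    D[ok] = np.fft.rfft(e)[ok] / K[ok]
    d = np.fft.irfft(D, n=n)
    return normalize_trial(d, window if window is not None else slice(None))


def convolve_reference(
    p: np.ndarray,
    kernel: DeconvKernel,
    window: slice | None = None,
) -> np.ndarray:
    """Forward model of the slow sensor: c = F^-1(p^ * k^), then normalized.

    Used to compare a fast reference recording (PID) to the raw sensor on
    the sensor's own time scale during kernel calibration.
    """
    p = np.asarray(p, dtype=float)
    K = _kernel_spectrum(kernel, p.size)
    c = np.fft.irfft(np.fft.rfft(p) * K, n=p.size)
    return normalize_trial(c, window if window is not None else slice(None))


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    tau_rise: float
    tau_decay: float
    objective: np.ndarray  # (len(tau_rise_grid), len(tau_decay_grid))
    tau_rise_grid: np.ndarray
    tau_decay_grid: np.ndarray


def default_tau_grids(n: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced calibration grids: rise in [1e-4, 1e-1] s, decay in [0.1, 2] s."""
    return (
        np.geomspace(1e-4, 1e-1, n),
        np.geomspace(0.1, 2.0, n),
    )


def calibrate_kernel(
    e_trials: np.ndarray,
    p_trials: np.ndarray,
    fs: float,
    window: slice,
    tau_rise_grid: np.ndarray | None = None,
    tau_decay_grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Grid-search the kernel time constants against a paired fast reference.

    For each (tau_rise, tau_decay) the normalized reference ``p`` is
    convolved with the candidate kernel and the objective is the mean over
    trials of ||e - normalize(c)||^2, where ``e`` is the normalized raw
    sensor.  Returns the argmin and the full objective surface.
    """
    e_trials = np.atleast_2d(np.asarray(e_trials, dtype=float))
    p_trials = np.atleast_2d(np.asarray(p_trials, dtype=float))
    if e_trials.shape != p_trials.shape:
        raise ValueError("paired sensor/reference trials must share a shape")
    if tau_rise_grid is None or tau_decay_grid is None:
        tr_def, td_def = default_tau_grids()
        tau_rise_grid = tr_def if tau_rise_grid is None else np.asarray(tau_rise_grid)
        tau_decay_grid = td_def if tau_decay_grid is None else np.asarray(tau_decay_grid)
    if tau_rise_grid.size == 0 or tau_decay_grid.size == 0:
        raise ValueError("empty calibration grid")

    n = e_trials.shape[1]
    e_norm = np.stack([normalize_trial(e, window) for e in e_trials])
    P = np.fft.rfft(
        np.stack([normalize_trial(p, window) for p in p_trials]), axis=1
    )
    objective = np.full((tau_rise_grid.size, tau_decay_grid.size), np.inf)
    for i, tr in enumerate(tau_rise_grid):
        for j, td in enumerate(tau_decay_grid):
            if td <= tr:
                continue
            K = _kernel_spectrum(build_kernel(tr, td, fs, n), n)
            c = np.fft.irfft(P * K, n=n, axis=1)
            seg = c[:, window]
            sd = seg.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                continue
            c = (c - seg.mean(axis=1, keepdims=True)) / sd
            objective[i, j] = np.mean(np.sum((e_norm - c) ** 2, axis=1))
    if not np.isfinite(objective).any():
        raise ValueError("objective surface is degenerate on the whole grid")
    i, j = np.unravel_index(np.argmin(objective), objective.shape)
    return CalibrationResult(
        tau_rise=float(tau_rise_grid[i]),
        tau_decay=float(tau_decay_grid[j]),
        objective=objective,
        tau_rise_grid=np.asarray(tau_rise_grid, dtype=float),
        tau_decay_grid=np.asarray(tau_decay_grid, dtype=float),
    )


# ---------------------------------------------------------------------------
# downsampling


def downsample_to_frames(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Average all fast samples falling in each camera-frame interval.

    Frame f covers the half-open interval [f/fs_out, (f+1)/fs_out); each
    output sample is the mean of the fast samples in that interval.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_frames = int(np.floor(n * fs_out / fs_in))
    edges = np.ceil(np.arange(n_frames + 1) * fs_in / fs_out - 1e-9).astype(int)
    if np.any(np.diff(edges) < 1):
        raise ValueError("empty camera-frame interval; fs_out exceeds fs_in")
    csum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    sums = csum[..., edges[1:]] - csum[..., edges[:-1]]
    return sums / np.diff(edges)


def recovery_within_one_step(recovered: float, truth: float, grid: np.ndarray) -> bool:
    """True when a calibrated constant lands within one grid step of truth."""
    grid = np.sort(np.asarray(grid, dtype=float))
    idx_true = int(np.argmin(np.abs(np.log(grid) - np.log(truth))))
    idx_rec = int(np.argmin(np.abs(np.log(grid) - np.log(recovered))))
    return abs(idx_rec - idx_true) <= 1
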