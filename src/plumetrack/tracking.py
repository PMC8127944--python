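"""Stimulus-response cross-correlation (plume tracking).

For each glomerulus the per-trial Pearson correlation between the
deconvolved odor signal and the deconvolved calcium rate is computed at
every lag over the middle 8 s of the plume, averaged across trials, and the
tracking statistic r_g is the maximum of that mean correlogram over lags in
(0, 500 ms] — neural activity following the odor.  Null distributions come
from non-matched trial pairings (trial shuffling): tracking reflects the
dynamics unique to each plume, not the shared statistics of the stimulus
ensemble, so shuffling destroys it while preserving everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    out = np.divide(a, sd, out=np.full_like(a, np.nan), where=sd > 0)
    return out


def xcorr_trial(
    e: np.ndarray,
    c: np.ndarray,
    max_lag: int,
    min_overlap: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged Pearson correlation between one trial's odor and response.

    Positive lag means the neural signal is delayed relative to the odor.
    Both segments are mean-subtracted per overlap, so each value is the
    Pearson coefficient of the overlapping samples.  Lags whose overlap is
    below ``min_overlap`` of the window, or with zero variance, are NaN.

    Returns (lags, r) with lags in samples from -max_lag to +max_lag.
    """
    e = np.asarray(e, dtype=float)
    c = np.asarray(c, dtype=float)
    if e.shape != c.shape:
        raise ValueError("signals must share a length")
    n = e.size
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            a, b = e[: n - lag], c[lag:]
        else:
            a, b = e[-lag:], c[: n + lag]
        if a.size < max(2, int(min_overlap * n)):
            continue
        if a.std() == 0 or b.std() == 0:
            continue
        r[idx] = float(np.corrcoef(a, b)[0, 1])
    return lags, r


def pairwise_correlograms(
    e_trials: np.ndarray, c_trials: np.ndarray, max_lag: int
) -> np.ndarray:
    """R[i, j, l]: correlation of odor trial i with response trial j at lag l.

    Vectorized over all ordered trial pairs; the matched correlograms are
    the diagonal, shuffled/bootstrap nulls draw from the off-diagonal.
    Lag axis runs -max_lag..+max_lag.
    """
    e_trials = np.atleast_2d(np.asarray(e_trials, dtype=float))
    c_trials = np.atleast_2d(np.asarray(c_trials, dtype=float))
    n_tr, n = e_trials.shape
    lags = np.arange(-max_lag, max_lag + 1)
    R = np.full((n_tr, c_trials.shape[0], lags.size), np.nan)
    for idx, lag in enumerate(lags):
        if lag >= 0:
            a = _standardize_rows(e_trials[:, : n - lag])
            b = _standardize_rows(c_trials[:, lag:])
        else:
            a = _standardize_rows(e_trials[:, -lag:])
            b = _standardize_rows(c_trials[:, : n + lag])
        R[:, :, idx] = a @ b.T / a.shape[1]
    return R


def aggregate_rg(
    correlograms: np.ndarray, max_lag: int, fs: float
) -> tuple[float, float]:
    """Trial-averaged correlogram maximum over lags 0 < l <= max_lag.

    ``correlograms`` is (n_trials, 2*max_lag+1).  Returns (r_g, lag_s).
    """
    correlograms = np.atleast_2d(correlograms)
    if correlograms.shape[0] < 1:
        raise ValueError("no trials in condition")
    mean_corr = np.nanmean(correlograms, axis=0)
    window = mean_corr[max_lag + 1 :]  # strictly positive lags
    best = int(np.nanargmax(window))
    return float(window[best]), float((best + 1) / fs)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffled_rg(
    R: np.ndarray,
    max_lag: int,
    fs: float,
    scheme: str = "derangement",
    rng: np.random.Generator | None = None,
) -> float:
    """Tracking statistic under one non-matched trial pairing.

    ``scheme="derangement"`` pairs each odor trial with a different trial's
    response (single shuffle); ``scheme="exhaustive"`` averages over all
    ordered non-matched pairs.
    """
    n = R.shape[0]
    if n < 3:
        raise ValueError("trial shuffling needs at least 3 trials")
    if scheme == "derangement":
        if rng is None:
            rng = np.random.default_rng()
        perm = _derangement(n, rng)
        corr = R[np.arange(n), perm, :]
    elif scheme == "exhaustive":
        off = ~np.eye(n, dtype=bool)
        corr = R[off, :]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return aggregate_rg(corr, max_lag, fs)[0]


@dataclass
class BootstrapNull:
    values: np.ndarray
    mean: float
    sd: float
    ci: tuple[float, float]


def bootstrap_null(
    R: np.ndarray,
    max_lag: int,
    fs: float,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    scheme: str = "derangement",
) -> BootstrapNull:
    """Null distribution of the shuffled tracking statistic.

    Each bootstrap draw forms one non-matched pairing of all trials
    (a random derangement by default; ``scheme="replacement"`` samples
    off-diagonal pairs with replacement), averages the paired correlograms,
    and takes the lag-window maximum.  The 95% CI is the [2.5, 97.5]
    percentile span of the draws.
    """
    if n_boot < 100:
        raise ValueError("bootstrap needs at least 100 iterations")
    if rng is None:
        rng = np.random.default_rng()
    n = R.shape[0]
    if n < 3:
        raise ValueError("trial shuffling needs at least 3 trials")
    L = R.shape[2]
    window = slice(max_lag + 1, L)

    if scheme == "derangement":
        perms = np.empty((n_boot, n), dtype=int)
        filled = 0
        while filled < n_boot:
            batch = np.argsort(rng.random((n_boot - filled, n)), axis=1)
            good = ~np.any(batch == np.arange(n), axis=1)
            take = batch[good]
            perms[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        rows = np.broadcast_to(np.arange(n), (n_boot, n))
        draws = R[rows, perms, :]  # (n_boot, n, L)
    elif scheme == "replacement":
        i = rng.integers(0, n, size=(n_boot, n))
        j = rng.integers(0, n - 1, size=(n_boot, n))
        j = np.where(j >= i, j + 1, j)  # never self-paired
        draws = R[i, j, :]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    mean_corr = np.nanmean(draws, axis=1)  # (n_boot, L)
    values = np.nanmax(mean_corr[:, window], axis=1)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return BootstrapNull(
        values=values, mean=float(values.mean()), sd=float(values.std()),
        ci=(float(lo), float(hi)),
    )


@dataclass
class TrackingResult:
    """Tracking summary for one glomerulus in one flow condition."""

    r_g: float
    lag_s: float
    shuffled_r_g: float
    null_mean: float
    null_sd: float
    ci: tuple[float, float]
    significant: bool  # matched r_g above the null 97.5th percentile
    outside_ci: bool  # matched r_g outside the two-sided 95% CI


def track_glomerulus(
    e_trials: np.ndarray,
    c_trials: np.ndarray,
    max_lag: int,
    fs: float,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    scheme: str = "derangement",
) -> TrackingResult:
    """Full matched/shuffled/bootstrap analysis for one glomerulus."""
    if rng is None:
        rng = np.random.default_rng()
    R = pairwise_correlograms(e_trials, c_trials, max_lag)
    n = R.shape[0]
    matched = R[np.arange(n), np.arange(n), :]
    r_g, lag_s = aggregate_rg(matched, max_lag, fs)
    shuf = shuffled_rg(R, max_lag, fs, rng=rng)
    null = bootstrap_null(R, max_lag, fs, n_boot=n_boot, rng=rng, scheme=scheme)
    return TrackingResult(
        r_g=r_g,
        lag_s=lag_s,
        shuffled_r_g=shuf,
        null_mean=null.mean,
        null_sd=null.sd,
        ci=null.ci,
        significant=bool(r_g > null.ci[1]),
        outside_ci=bool(r_g > null.ci[1] or r_g < null.ci[0]),
    )


def condition_contrast(
    rg_high: np.ndarray, rg_low: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Paired per-glomerulus tracking difference (high - low) and t-test."""
    rg_high = np.asarray(rg_high, dtype=float)
    rg_low = np.asarray(rg_low, dtype=float)
    if rg_high.shape != rg_low.shape:
        raise ValueError("paired conditions must align per glomerulus")
    delta = rg_high - rg_low
    if np.allclose(delta, 0):
        return delta, 0.0, 1.0
    t, p = sps.ttest_rel(rg_high, rg_low)
    return delta, float(t), float(p)
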