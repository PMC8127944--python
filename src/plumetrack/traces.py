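"""Glomerular calcium-trace conditioning.

Stages, in order: per-trial baseline normalization (z-score by the 5 s
pre-stimulus window), ROI merge screening (over-segmentation guard),
nonnegative sparse deconvolution of the indicator kernel with an L1 rate
penalty, and whole-trace standardization.  ``extract_roi_traces`` provides
pixel-mean traces from synthetic movies so the pipeline can run end-to-end
without an upstream segmentation step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .sensor import DeconvKernel, DegenerateTrialError


def baseline_normalize(trace: np.ndarray, baseline: slice) -> np.ndarray:
    """Z-score a trial trace by its pre-stimulus baseline mean/SD."""
    trace = np.asarray(trace, dtype=float)
    seg = trace[baseline]
    if seg.size < 2:
        raise ValueError("baseline window needs at least 2 samples")
    sd = seg.std()
    if sd == 0:
        raise DegenerateTrialError("zero baseline standard deviation")
    return (trace - seg.mean()) / sd


def standardize_trace(trace: np.ndarray) -> np.ndarray:
    """Divide by the whole-trace SD (no mean subtraction).

    Puts glomeruli with different expression levels and depths on a common
    scale without moving the zero of the deconvolved rate.
    """
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    if sd == 0:
        raise DegenerateTrialError("zero whole-trace standard deviation")
    return trace / sd


# ---------------------------------------------------------------------------
# ROI merging


@dataclass
class MergeDecision:
    pair: tuple[int, int]
    baseline_correlation: float
    binarized_correlation: float | None
    dropped: int | None


def _binarize(x: np.ndarray) -> np.ndarray:
    """1 where activity leaves the +/- 1 SD band around its mean, else 0."""
    return (np.abs(x - x.mean()) > x.std()).astype(float)


def merge_rois(
    baseline_traces: np.ndarray,
    mean_activity: np.ndarray,
    adjacency: set[tuple[int, int]] | None = None,
    threshold: float = 0.75,
) -> tuple[list[int], list[MergeDecision]]:
    """Two-stage over-segmentation screen on neighboring ROIs.

    A neighboring pair whose baseline traces correlate strictly above
    ``threshold`` is a merge candidate; if the correlation of their +/-1 SD
    binarized baseline traces also strictly exceeds it, the member with the
    lower mean activity is dropped.  Returns kept indices and the full
    decision log.

    ``baseline_traces`` is (n_rois, n_baseline_samples) — baseline periods
    concatenated across trials.  ``adjacency`` is a set of index pairs; None
    treats every pair as neighboring.
    """
    baseline_traces = np.asarray(baseline_traces, dtype=float)
    mean_activity = np.asarray(mean_activity, dtype=float)
    n = baseline_traces.shape[0]
    if adjacency is None:
        adjacency = {(i, j) for i in range(n) for j in range(i + 1, n)}
    decisions: list[MergeDecision] = []
    dropped: set[int] = set()
    for i, j in sorted(adjacency):
        if i in dropped or j in dropped:
            continue
        r = float(np.corrcoef(baseline_traces[i], baseline_traces[j])[0, 1])
        if not r > threshold:
            decisions.append(MergeDecision((i, j), r, None, None))
            continue
        bi, bj = _binarize(baseline_traces[i]), _binarize(baseline_traces[j])
        if bi.std() == 0 or bj.std() == 0:
            rb = 0.0
        else:
            rb = float(np.corrcoef(bi, bj)[0, 1])
        drop = None
        if rb > threshold:
            drop = i if mean_activity[i] < mean_activity[j] else j
            dropped.add(drop)
        decisions.append(MergeDecision((i, j), r, rb, drop))
    kept = [g for g in range(n) if g not in dropped]
    return kept, decisions


def centroid_adjacency(
    masks: list[np.ndarray], scale: float = 1.5
) -> set[tuple[int, int]]:
    """Pairs whose mask centroids are within ``scale`` x the mean ROI diameter."""
    cents, diams = [], []
    for m in masks:
        ys, xs = np.nonzero(m)
        if ys.size == 0:
            raise ValueError("empty mask")
        cents.append((ys.mean(), xs.mean()))
        diams.append(2.0 * np.sqrt(ys.size / np.pi))
    limit = scale * float(np.mean(diams))
    adj = set()
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            d = np.hypot(cents[i][0] - cents[j][0], cents[i][1] - cents[j][1])
            if d <= limit:
                adj.add((i, j))
    return adj


# ---------------------------------------------------------------------------
# sparse nonnegative deconvolution


def _conv(r: np.ndarray, k: np.ndarray) -> np.ndarray:
    return fftconvolve(r, k[None, :] if r.ndim == 2 else k, axes=-1)[..., : r.shape[-1]]

def _conv_t(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    kr = k[::-1]
    full = fftconvolve(y, kr[None, :] if y.ndim == 2 else kr, axes=-1)
    return full[..., k.size - 1 : k.size - 1 + y.shape[-1]]


def _truncated_kernel(kernel: DeconvKernel, n: int, span: float = 6.0) -> np.ndarray:
    """Discrete indicator kernel truncated at span * tau_decay, dt-scaled."""
    m = min(int(span * kernel.tau_decay * kernel.fs) + 1, n)
    return kernel.values[:m] * kernel.dt


def _operator_norm_sq(k: np.ndarray, n: int) -> float:
    # circular upper bound on ||K||^2 for the linear convolution operator
    kpad = np.zeros(n)
    kpad[: k.size] = k
    return float(np.max(np.abs(np.fft.fft(kpad)) ** 2))


def lambda_max(x: np.ndarray, kernel: DeconvKernel) -> float:
    """Smallest L1 penalty for which the optimal rate is identically zero."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k = _truncated_kernel(kernel, x.shape[-1])
    return float(np.max(2.0 * _conv_t(x, k)))


def sparse_deconvolve(
    x: np.ndarray,
    lam: float,
    kernel: DeconvKernel,
    tol: float = 1e-8,
    max_iter: int = 4000,
) -> np.ndarray:
    """Nonnegative L1-penalized deconvolution of the indicator kernel.

    Solves argmin_{r >= 0} ||x - r * k||^2 + lam * ||r||_1 by FISTA with a
    nonnegative soft-threshold prox.  ``x`` may be (n,) or (trials, n);
    trials are solved jointly (the objective is separable across rows).
    Stops when the relative objective decrease falls below ``tol``; raises
    with diagnostics if ``max_iter`` is exhausted first.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    n = X.shape[-1]
    k = _truncated_kernel(kernel, n)
    L = 2.0 * _operator_norm_sq(k, n) * 1.01
    step = 1.0 / L

    def objective(r):
        resid = X - _conv(r, k)
        return float(np.sum(resid**2) + lam * np.sum(r))

    r = np.zeros_like(X)
    z = r.copy()
    t = 1.0
    prev = objective(r)
    for it in range(max_iter):
        grad = 2.0 * _conv_t(_conv(z, k) - X, k)
        r_new = np.maximum(0.0, z - step * grad - step * lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = r_new + ((t - 1.0) / t_new) * (r_new - r)
        r, t = r_new, t_new
        cur = objective(r)
        if cur > prev:  # restart momentum on non-monotone step
            z, t = r.copy(), 1.0
        if abs(prev - cur) <= tol * max(abs(prev), 1e-12):
            break
        prev = cur
    else:
        raise RuntimeError(
            f"sparse deconvolution did not converge: {max_iter} iterations, "
            f"objective {cur:.6g}, last decrease {prev - cur:.3g}"
        )
    return r[0] if single else r


def select_lambda(
    traces_by_glom: list[np.ndarray],
    kernel: DeconvKernel,
    baseline: slice,
    n_grid: int = 8,
    silent_fraction: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> tuple[float, np.ndarray]:
    """Session penalty: median over per-glomerulus optimized penalties.

    For each glomerulus the per-unit penalty is the smallest value for which
    the deconvolved rate is silent in at least ``silent_fraction`` of
    baseline frames — encoding "no events without stimulus".  The search
    walks a log grid of fractions of that glomerulus's lambda_max and then
    bisects between the first silent grid point and its predecessor.
    Returns (lambda_session, per-glomerulus lambdas).
    """
    if not traces_by_glom:
        raise ValueError("need at least one glomerulus")

    def silent(trials, lam):
        r = sparse_deconvolve(trials, lam, kernel, tol=tol, max_iter=max_iter)
        return np.mean(r[:, baseline] <= 1e-12) >= silent_fraction

    lam_g = np.zeros(len(traces_by_glom))
    for g, trials in enumerate(traces_by_glom):
        trials = np.atleast_2d(np.asarray(trials, dtype=float))
        lmax = lambda_max(trials, kernel)
        grid = lmax * np.geomspace(1e-3, 1.0, n_grid)
        chosen, lo = lmax, 0.0
        for i, lam in enumerate(grid):
            if silent(trials, lam):
                chosen = lam
                lo = grid[i - 1] if i > 0 else 0.0
                break
        for _ in range(3):  # refine toward the smallest silent penalty
            mid = 0.5 * (lo + chosen)
            if silent(trials, mid):
                chosen = mid
            else:
                lo = mid
        lam_g[g] = chosen
    return float(np.median(lam_g)), lam_g


# ---------------------------------------------------------------------------
# movie ROI extraction


def extract_roi_traces(movie: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-mean trace per ROI from a (T, H, W) movie."""
    movie = np.asarray(movie, dtype=float)
    out = np.zeros((len(masks), movie.shape[0]))
    for g, mask in enumerate(masks):
        if not mask.any():
            raise ValueError(f"mask {g} is empty")
        out[g] = movie[:, mask].mean(axis=1)
    return out
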