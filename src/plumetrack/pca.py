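"""Whole field-of-view PCA on movie pixels.

Population activity is examined without segmentation: each trial's movie is
unfolded to a pixel x time matrix, mean-centered per pixel and decomposed by
SVD.  A component whose score time series correlates with the deconvolved
odor signal (at short positive lags) identifies odor-tracking population
activity, and its loading map shows where in the bulb it lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import xcorr_trial


@dataclass
class PCAResult:
    scores: np.ndarray  # (k, T) component time series
    loadings: np.ndarray  # (n_pixels, k) pixel maps
    variance_explained: np.ndarray  # (k,), nonincreasing


def pca_decompose(matrix: np.ndarray, k: int) -> PCAResult:
    """Mean-centered SVD of a (pixels x time) matrix.

    Deterministic up to sign; the sign of each component is fixed so that
    its largest-magnitude loading is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(matrix.shape)}")
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    u = u * flip
    vt = vt * flip[:, None]
    t = matrix.shape[1]
    return PCAResult(
        scores=s[:, None] * vt,
        loadings=u,
        variance_explained=s**2 / t,
    )


def component_odor_correlation(
    scores: np.ndarray, odor: np.ndarray, max_lag: int
) -> tuple[np.ndarray, int]:
    """Max correlation of each component with the odor over lags 0..max_lag.

    ``odor`` must already be on the imaging clock (frame-averaged to 30 Hz).
    Returns (per-component max correlation over 0 <= l <= max_lag, index of
    the best component).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    odor = np.asarray(odor, dtype=float)
    if scores.shape[1] != odor.size:
        raise ValueError("scores and odor trace must share a sampling grid")
    best = np.full(scores.shape[0], np.nan)
    for i, comp in enumerate(scores):
        _, r = xcorr_trial(odor, comp, max_lag)
        best[i] = np.nanmax(r[max_lag:])
    return best, int(np.nanargmax(best))


def loading_map_dice(loading: np.ndarray, truth_mask: np.ndarray, top_fraction: float | None = None) -> float:
    """Dice overlap between a thresholded loading map and a ground-truth mask.

    The loading map is binarized at its top-|truth| pixel count unless a
    fraction is given.
    """
    loading = np.asarray(loading, dtype=float).ravel()
    truth = np.asarray(truth_mask, dtype=bool).ravel()
    n_top = int(top_fraction * loading.size) if top_fraction else int(truth.sum())
    idx = np.argsort(np.abs(loading))[::-1][:n_top]
    pred = np.zeros_like(truth)
    pred[idx] = True
    inter = np.logical_and(pred, truth).sum()
    return float(2.0 * inter / (pred.sum() + truth.sum()))
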