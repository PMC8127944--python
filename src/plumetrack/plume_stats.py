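"""Per-trial plume intermittency statistics and flow-condition comparisons.

Turbulent plumes alternate between whiffs (high-concentration excursions)
and blanks; that intermittency shows up as positive skewness and asymmetry
of the within-trial concentration distribution, and grows with airflow.
Statistics are computed over the middle 8 s of the 10 s plume so onset and
offset transients (including the deconvolution's onset artifact) are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def skewness(x: np.ndarray) -> float:
    """Standardized third central moment m3 / m2^(3/2).

    Zero for any symmetric distribution; positive for whiff/blank
    intermittency.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 samples")
    if x.std() == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(sps.skew(x, bias=True))


def asymmetry(x: np.ndarray, method: str = "mean_median") -> float:
    """Nonparametric asymmetry of the sample distribution.

    Default is the (mean - median) / SD nonparametric skew; the unscaled
    third central moment is available via ``method="third_moment"``.  Both
    vanish for symmetric distributions.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("asymmetry needs at least 3 samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("asymmetry undefined for zero-variance sample")
    if method == "mean_median":
        return float((x.mean() - np.median(x)) / sd)
    if method == "third_moment":
        return float(np.mean((x - x.mean()) ** 3))
    raise ValueError(f"unknown asymmetry method {method!r}")


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    power: np.ndarray  # one-sided, sums to the window variance
    band_power: float
    band_fraction: float


def band_spectrum(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.0, 5.0)
) -> SpectrumResult:
    """One-sided periodogram normalized so the spectral sum equals the
    sample variance (Parseval), plus cumulative power in ``band``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < fs:
        raise ValueError("window shorter than 1 s")
    if band[1] > fs / 2:
        raise ValueError("band extends above Nyquist")
    xc = x - x.mean()
    spec = np.abs(np.fft.rfft(xc)) ** 2 / n**2
    # fold negative frequencies onto positive bins (DC/Nyquist not doubled)
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    total = spec.sum()
    band_power = float(spec[in_band].sum())
    return SpectrumResult(
        freqs=freqs,
        power=spec,
        band_power=band_power,
        band_fraction=float(band_power / total) if total > 0 else np.nan,
    )


@dataclass
class FlowComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, reject (at alpha)
    alpha: float


def compare_flows(
    values: np.ndarray, labels: list[str], alpha: float = 0.01
) -> FlowComparison:
    """One-way ANOVA across flow conditions plus Tukey pairwise decisions."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == lab] for lab in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two flow conditions")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every flow condition needs at least two trials")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical constant groups: no variance anywhere, nothing to test
        pairwise = pd.DataFrame(columns=["group1", "group2", "meandiff", "reject"])
        return FlowComparison(0.0, 1.0, pairwise, alpha)
    f, p = sps.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )[["group1", "group2", "meandiff", "reject"]]
    return FlowComparison(float(f), float(p), table, alpha)


def trial_stats_table(
    conc_windows: list[np.ndarray], flow_labels: list[str], fs: float
) -> pd.DataFrame:
    """One row per trial: skewness, asymmetry, 0-5 Hz power, mean."""
    rows = []
    for i, (w, lab) in enumerate(zip(conc_windows, flow_labels)):
        spec = band_spectrum(w, fs)
        rows.append(
            {
                "trial": i,
                "flow": lab,
                "skewness": skewness(w),
                "asymmetry": asymmetry(w),
                "band_power_0_5": spec.band_power,
                "band_fraction_0_5": spec.band_fraction,
                "mean_concentration": float(np.mean(w)),
            }
        )
    return pd.DataFrame(rows)
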