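# plumetrack

Analysis of how turbulent odor-plume dynamics structure mitral/tufted (MT)
glomerular activity in the mouse olfactory bulb, rebuilt as a tested Python
pipeline and exercised end-to-end on a synthetic session generator with full
ground truth.

In the experiment this pipeline models, a head-fixed mouse sits in a wind
tunnel while 10 s ethanol plumes are released upwind under low, medium or
high airflow. A slow metal-oxide (MOX) odor sensor at the nostril records
concentration at 100 Hz, and widefield GCaMP6f imaging records glomerular
fluorescence at 30 Hz. The analysis asks how faithfully each glomerulus
follows the plume's concentration fluctuations, and how the airflow regime —
which sets the plume's intermittency — moderates that tracking.

## The core computations

**Sensor deconvolution.** The MOX sensor responds through slow first-order
kinetics. Its response kernel is a normalized double exponential

    k0(t) = exp(-t/τ_decay) - exp(-t/τ_rise),    k = k0 / ∫ k0,

with defaults τ_decay = 0.4629 s, τ_rise = 0.0001 s, and the fast
concentration signal is recovered by spectral division d = F⁻¹(ê/k̂) after a
30 Hz Kaiser low-pass and per-trial normalization by the plume-window
mean/SD. The kernel can be recalibrated against a paired fast (PID-like)
reference by a log-grid search minimizing ‖e − normalize(p ⊛ k)‖² averaged
over trials.

**Plume intermittency.** Within the middle 8 s of each plume, intermittency
is quantified by the skewness m₃/m₂^{3/2} and a nonparametric asymmetry
(mean − median)/SD of the concentration distribution — both zero for
symmetric fluctuations, positive for whiff/blank structure — and compared
across flows by one-way ANOVA with Tukey pairwise decisions at p < 0.01.

**Trace conditioning.** Glomerular traces are z-scored by the 5 s
pre-stimulus baseline, screened for over-segmentation (neighboring ROIs
whose raw and ±1 SD-binarized baseline correlations both exceed 0.75 lose
the lower-mean member), deconvolved to nonnegative activity rates by
L1-penalized least squares r* = argmin_{r≥0} ‖x − r⊛k‖² + λ‖r‖₁ with the
session λ set to the median of per-glomerulus penalties that silence the
baseline, and standardized by each glomerulus's whole-trace SD.

**Tracking statistic.** For glomerulus g, Pearson correlations r_{g,n,l}
between the deconvolved odor and response are computed at every lag l
within each trial n, averaged across trials, and summarized as

    r_g = max_{0 < l ≤ 500 ms} r̄_{g,l},

i.e. the best correlation with the neural signal lagging the odor.
Significance comes from a 10,000-draw bootstrap null built from non-matched
trial pairings (random derangements), with a single-shuffle comparison for
plotting.

**Responsivity and band power.** A trial is "responsive" when the count of
|z| > 1.96 time points during the plume + 1 s exceeds ⌈5% of the window⌉
(strict); responsivity is the responsive-trial proportion per flow
condition. Response power is the 0–5 Hz band of a variance-normalized
periodogram (Parseval), compared plume-vs-baseline, with a 75th-percentile
strong-responder subset contrast. Whole-FOV pixel PCA identifies the
odor-tracking population component without any segmentation.

## Layout

- `src/plumetrack/` — the library: `synth` (session generator),
  `sensor`, `plume_stats`, `traces`, `tracking`, `metrics`, `pca`,
  `pipeline` (orchestration + stats report), `io`, `validation`.
- `analysis/01…07` — numbered drivers that run the study on a default
  synthetic session and write tables under `results/`.
- `tests/` — the pytest suite, including `test_acceptance.py`.

## Worked example

```bash
python analysis/01_simulate_session.py
python analysis/03_plume_statistics.py
python analysis/05_tracking.py
```

prints (seed 1, default 40-trial session with 20 glomeruli):

```
        skewness  asymmetry  band_fraction_0_5  mean_concentration
flow
high       2.764      0.292              0.897               0.010
low        0.141      0.012              0.754               0.115
medium     2.420      0.354              0.911              -0.001
skewness: F = 40.2, p = 5.3e-10
  high vs low: diff -2.62, reject True
  high vs medium: diff -0.34, reject False

significant tracking (all/low/high): {'all': '16/20', 'high': '17/20', 'low': '16/20'}
mean r_g: low 0.067, high 0.214  (paired t(19) = 6.55, p = 2.9e-06)
mean argmax lag: 145 ms
```

Read: high- and medium-flow plumes are strongly skewed (intermittent
whiff/blank structure) while low flow is near-symmetric, and only the
low-vs-turbulent contrasts separate statistically. Most glomeruli track the
plume significantly against their trial-shuffled null, tracking is about
three times stronger under high flow, and the recovered response lag sits
near 150 ms. The mean concentration column is ≈0 because the deconvolved
signal is z-scored within the plume window; the raw-concentration means (low
≈ 2× high) are in `results/plume_stats.csv`.

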