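# Methods

This note documents the models, parameter choices and numerical conventions
behind `plumetrack`, and what the synthetic-data results do and do not say
about real recordings.

## Synthetic sessions

The generator (`plumetrack.synth`) emulates the statistical structure of
wind-tunnel imaging sessions, not their fluid dynamics. A session is 40
trials — 10 at medium flow, then alternating high/low blocks of five (the
starting block is configurable) — each ~30 s long with a 10 s plume whose
onset is jittered uniformly within ±2 s of the 10 s mark. Channels: ground
truth concentration and a slow-sensor reading at 100 Hz, an optional fast
reference (concentration plus white noise, emulating a PID), and 30 Hz
fluorescence per glomerulus. All randomness derives from one session seed
via numpy `SeedSequence` spawning (one child per trial; within a trial, one
child each for concentration, sensor, reference, and every glomerulus), so
identical (config, seed) pairs are bit-identical.

**Plume model.** Within the plume window, whiff onsets form a Poisson
process with lognormal durations and amplitudes; the superposition rides on
a constant background, is smoothed by a first-order filter
(`fluctuation_timescale`), gets small Gaussian measurement noise, and is
clipped nonnegative and zeroed outside the window. Two refinements model
plume meander at the sensor: under turbulent presets the per-trial whiff
rate is gamma-mixed (shape `rate_dispersion`, floored at a quarter of
nominal), and every released plume sheds at least two whiffs — a release a
dozen centimeters upwind essentially never misses the sensor completely.

**Flow presets.** The presets encode the observed flow contrast as a
direction, not a magnitude: low flow is dense and near-symmetric (rate
3 /s, duration ≈ 0.57 s, small amplitude variance, background 0.5,
smoothing 0.3 s), high flow is sparse and spiky (rate 0.9 /s with
dispersion 1.2, duration ≈ 0.27 s, large amplitude variance, background
0.03, smoothing 0.06 s), and medium sits with high, as the recorded
medium/high conditions were statistically inseparable. Under these presets
high-flow skewness exceeds low-flow skewness by >2 on average (win
probability ≈ 0.995 per trial pair) and the high-flow plume-window mean is
≈ 55% of the low-flow mean, mirroring the reported direction of the mean
concentration decrease. Tunnel airspeeds are carried as metadata only;
Reynolds numbers are not recomputed, since the printed velocities and
Reynolds numbers cannot be reconciled with standard air viscosity and the
analysis never consumes them.

**Glomeruli.** Each glomerulus maps delayed concentration to an activity
rate, rate(t) = sat(g_track·conc(t−lag) + g_tonic·1[plume on]), with a soft
ceiling sat(x) = s·tanh(x/s) (default s = 2.5; `None` for linear), then
convolves the rate with a GCaMP6f-like double exponential (τ_rise 0.05 s,
τ_decay 0.4 s), frame-averages to 30 Hz, and adds Gaussian noise. The
default 20-unit population spans weak-to-strong responders (strength
log-spaced 0.1–0.5, imaging noise SD 0.1), with the tracking share of the
drive growing with strength and every fifth unit purely tonic. The strength
range deliberately puts much of the population near the noise floor — as in
real widefield data — which is what lets responsivity grade instead of
saturating; the tracking-share gradient builds in the observed positive
responsivity–tracking association. The tonic drive follows the release
window (not instantaneous odor presence), so purely tonic units are
"responsive but not tracking" by construction.

What the generator does *not* emulate: sniffing, correlated noise across
glomeruli, neuropil contamination, motion, bleaching, adaptation, and any
genuine odor transport physics. Passing tests therefore show the *analysis*
behaves correctly on data with the assumed statistical structure; they do
not validate the biological claims on real recordings.

## Sensor path

The raw 100 Hz sensor trace is low-passed at 30 Hz with a Kaiser-window FIR
(101 taps, β = 5 — the design parameters are a package choice, recorded in
metadata with the measured ripple/attenuation; the filter is linear-phase
and applied delay-compensated on a reflect-padded signal). Each trial is
z-scored by the mean/SD over the plume window, then deconvolved by spectral
division over the trial-length grid without padding; circular wrap is
accepted because downstream analyses exclude the first and last second of
the plume anyway, which also handles the deconvolution's known onset
inflection by exclusion rather than correction. Frequency bins where
|k̂| < 10⁻³·max|k̂| are zeroed instead of divided; with the default kernel
and trial length no bin reaches that threshold, so convolve-then-deconvolve
round trips are exact to ~10⁻¹⁴. Calibration normalizes the convolved
reference over the plume window (symmetric with the sensor normalization; a
config switch allows whole-trial statistics). Downsampling to the imaging
clock averages the 100 Hz samples in each half-open frame interval.

Sensor drift biases the calibration objective toward slow kernels: the
whole-trial MSE rewards kernels that smear signal into the drifting
baseline. Recovery within one grid step of the true decay constant
(20-point log grids over τ_rise ∈ [10⁻⁴, 10⁻¹], τ_decay ∈ [0.1, 2.0])
therefore assumes a stable calibration rig — drift an order of magnitude
below the recording sessions — which matches how a dedicated paired
calibration recording is actually made.

## Trace processing

Stages run strictly in order: per-trial baseline z-score (5 s pre-stimulus
window), merge screen, sparse deconvolution, whole-trace standardization.
The merge screen is a guard against over-segmentation: neighboring ROIs
(centroids within 1.5× the mean ROI diameter, configurable) are dropped
pairwise when baseline correlation and ±1 SD-binarized baseline correlation
both *strictly* exceed 0.75 — all thresholds in this package use strict
inequalities — keeping the higher-mean member.

Sparse deconvolution solves argmin_{r≥0} ‖x − r⊛k‖² + λ‖r‖₁ by FISTA with a
nonnegative soft-threshold prox, momentum restart on non-monotone steps,
step size from a circular bound on the operator norm, and a relative
objective tolerance of 10⁻⁸ (4000-iteration cap, error with diagnostics on
non-convergence). Trials of one glomerulus are solved jointly as a batch;
the objective is separable, so the batch optimum matches per-trial solves.
The per-glomerulus penalty is the smallest λ (log grid of fractions of that
glomerulus's λ_max, bisection-refined) for which the deconvolved rate is
silent in ≥95% of baseline frames — encoding "no events without stimulus" —
and the session penalty is the median across glomeruli, applied to all
(whole-session optimization; a per-trial variant was considered and
rejected as noisier). λ_max = 2·max(kᵀx) is the smallest penalty with an
all-zero optimum.

Two consequences of the exactly-sparse formulation are worth flagging.
First, the deconvolved baseline is genuinely zero, so the ±1.96
baseline-band responsivity rule would become binary at that stage; events
are therefore counted on the baseline-normalized stage, where the
threshold's chance calibration (5% exceedance under a Gaussian null) holds.
Second, the rate estimate concentrates mass into impulsive events whose
spectrum is broadband, so band fractions of *estimated* rates run lower
than those of the smooth underlying rates; the >0.8 band-fraction property
is accordingly a statement about the generator's ground-truth rates. The
"deconvolution accelerates dynamics" property (deconvolved ≥ raw
correlation with ground-truth rate for ≥90% of glomeruli) is real but only
measurable when imaging noise is low enough for the indicator lag to be the
binding distortion; it is verified at noise SD 0.01.

## Tracking

Correlations use the middle 8 s of each plume on the 30 Hz clock (240
frames), with positive lag meaning the neural signal trails the odor; the
statistic takes the maximum of the trial-averaged correlogram over lags
0 < l ≤ 15 frames (500 ms), excluding lag zero by the definition's strict
inequality. Lags are computed on overlapping segments only, each segment
mean-subtracted (exact per-lag Pearson); lags with under 80% overlap are
dropped as missing.

The bootstrap null draws, per iteration, one random derangement of the
trial pairing — every trial used once, none matched with itself — and
pushes the deranged pairs through the identical average-then-maximize
pipeline. The derangement draw (rather than pairing with replacement) is
the default because it makes each null draw structurally identical to the
matched statistic (a permutation of the same pairing graph), so under the
no-tracking null the two-sided outside-CI rate calibrates at the nominal
5%; with-replacement pairing and exhaustive non-matched enumeration are
available as alternatives. Significance for the tracking flag is upper-tail
exceedance of the 97.5th percentile (the two-sided CI is reported
alongside), matching a question of tracking *above* chance.

## Metrics and PCA

Responsivity windows follow the definitions exactly: events are counted
over the plume plus 1 s (rebound window) with the chance threshold
⌈0.05·n⌉ computed from the same window, while mean response and tracking
use the middle 8 s — the two metrics intentionally use different windows.
The two-sided |z| > 1.96 event rule counts suppression as response. Band
power uses a periodogram normalized so the spectral sum equals the window
variance; band power is then intensive (window-length independent for
stationary signals), which is what makes the 5 s baseline and the longer
plume windows comparable without further normalization. The STFT view uses
a 1 s Hann window with 50% overlap and PSD scaling (package choices,
recorded in the function contract). PCA mean-centers pixels, decomposes by
SVD with signs fixed by the largest-magnitude loading, and correlates
component scores with the deconvolved odor over lags 0–500 ms per trial
(per-trial decomposition by default, matching single-trial correlograms).

## Pipeline and reporting

`RunConfig` carries every analysis constant at its stated default (0.75
merge threshold, 1.96 event threshold, 5% chance rate, 500 ms lag window,
0–5 Hz band, 75th percentile, 10,000 bootstrap draws); each output table
embeds a 12-hex-digit hash of the serialized session config, and reruns
with the same seed are byte-identical. The statistics report recomputes the
standard comparison suite (ANOVA + Tukey on plume statistics, paired t
tests for flow contrasts, responsivity- and power-versus-tracking Pearson
correlations, KS test comparing pixel-averaged versus deconvolved pairwise
trace-correlation distributions) on the session at hand, reporting raw
per-test p-values (an optional Holm correction flag exists but is off by
default). These values are session-specific; the original study's in vivo
magnitudes are not reproducible from synthetic data, and the package makes
no attempt to match them beyond direction.

## Problem sizes

Default problem sizes were chosen so every analysis runs comfortably on a
laptop core: 40-trial sessions with 20 glomeruli; 10 paired sessions of 10
trials for calibration recovery; 200 simulated glomeruli with 2,000
bootstrap draws for null calibration; 20 plume pairs for the skewness
contrast; 10⁶ samples for the Gaussian exceedance reference. The ANOVA
type-I calibration uses 300 replicates. Bootstrap defaults stay at 10,000
draws in the pipeline itself.

## Known limitations

- The generator targets summary statistics (skewness ordering, whiff/blank
  structure, 0–5 Hz-dominant spectra), not odor transport; absolute
  magnitudes of any statistic are not meaningful points of comparison.
- "Asymmetry" is implemented as (mean − median)/SD with an unscaled
  third-moment variant available; any measure vanishing under symmetry
  would serve.
- The 75th-percentile power contrast is reported but its direction is not a
  built-in property of the default generator (the strong-responder power
  increase under high flow depends on response nonlinearities the forward
  model only partly captures).
- Upstream segmentation (CNMF), motion correction and sniffing are out of
  scope; the pipeline consumes ROI traces, with ground-truth-mask
  extraction provided for synthetic movies.
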