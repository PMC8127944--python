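"""Synthetic wind-tunnel imaging sessions with ground truth.

The generator emulates the statistical structure of the recorded sessions:
40-trial blocks of low/medium/high airflow, 10 s turbulent ethanol plumes
with jittered onsets inside ~30 s trials, a slow 100 Hz MOX sensor channel
(with an optional fast PID-like reference), and 30 Hz GCaMP fluorescence for
a population of glomeruli whose responses mix concentration tracking and
tonic odor-presence components.

Plumes are modeled as a Poisson process of whiffs with lognormal durations
and amplitudes, superposed, smoothed by a first-order filter and riding on a
flow-dependent background.  The presets target the observed flow contrast:
low flow gives a dense, near-symmetric concentration distribution; high flow
gives sparse large whiffs separated by blanks (positively skewed), with a
lower plume-window mean concentration.  No fluid dynamics is simulated; the
generator targets the summary statistics the analysis consumes.

All randomness flows from a single session seed via numpy SeedSequence
spawning: one child per trial, and within each trial one child each for the
concentration, sensor noise, reference noise, and every glomerulus, in that
order.  Identical (config, seed) pairs yield bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sensor import DeconvKernel, build_kernel, downsample_to_frames

FLOW_LABELS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class FlowParams:
    """Whiff-process parameters for one airflow condition.

    whiff_duration and whiff_amplitude are lognormal: (mu, sigma) are the
    mean/SD of the underlying normal, so E[X] = exp(mu + sigma^2/2).
    """

    label: str
    whiff_rate: float  # events / s
    whiff_duration_mu: float
    whiff_duration_sigma: float
    whiff_amplitude_mu: float
    whiff_amplitude_sigma: float
    background_mean: float  # a.u., added inside the plume window
    fluctuation_timescale: float  # s, first-order smoothing
    noise_sd: float = 0.0
    # gamma shape of per-trial whiff-rate variability (plume meander);
    # None holds the rate fixed across trials
    rate_dispersion: float | None = None
    # metadata only (the analysis never recomputes Reynolds numbers)
    velocity_fpm: float | None = None

    def __post_init__(self):
        if self.label not in FLOW_LABELS:
            raise ValueError(f"flow label must be one of {FLOW_LABELS}")
        if self.whiff_rate < 0:
            raise ValueError("whiff_rate must be nonnegative")
        for name in ("whiff_duration_sigma", "whiff_amplitude_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.fluctuation_timescale <= 0:
            raise ValueError("fluctuation_timescale must be positive")
        if self.background_mean < 0:
            raise ValueError("background_mean must be nonnegative")


def default_flow_presets() -> dict[str, FlowParams]:
    """Shipped low/medium/high presets.

    Low flow: high whiff duty cycle, small amplitude variance and a large
    background -> dense plume, near-symmetric fluctuations, highest mean.
    High flow: sparse, short, large-amplitude whiffs over near-zero
    background -> intermittent whiff/blank structure, positive skewness and
    roughly half the low-flow plume-window mean.  Medium sits with high
    (turbulent) statistics, as observed.
    """
    return {
        "low": FlowParams(
            label="low",
            whiff_rate=3.0,
            whiff_duration_mu=np.log(0.55),
            whiff_duration_sigma=0.3,
            whiff_amplitude_mu=np.log(0.25),
            whiff_amplitude_sigma=0.15,
            background_mean=0.5,
            fluctuation_timescale=0.3,
            noise_sd=0.02,
            velocity_fpm=0.40,
        ),
        "medium": FlowParams(
            label="medium",
            whiff_rate=1.2,
            whiff_duration_mu=np.log(0.30),
            whiff_duration_sigma=0.4,
            whiff_amplitude_mu=np.log(1.30),
            whiff_amplitude_sigma=0.6,
            background_mean=0.08,
            fluctuation_timescale=0.08,
            noise_sd=0.02,
            rate_dispersion=2.0,
            velocity_fpm=1.31,
        ),
        "high": FlowParams(
            label="high",
            whiff_rate=0.9,
            whiff_duration_mu=np.log(0.25),
            whiff_duration_sigma=0.4,
            whiff_amplitude_mu=np.log(1.60),
            whiff_amplitude_sigma=0.7,
            background_mean=0.03,
            fluctuation_timescale=0.06,
            noise_sd=0.02,
            rate_dispersion=1.2,
            velocity_fpm=1.81,
        ),
    }


@dataclass(frozen=True)
class TrialTiming:
    """Clock layout of a single trial (seconds / Hz)."""

    trial_length: float = 30.0
    baseline_start: float = 0.0
    baseline_end: float = 5.0
    nominal_plume_onset: float = 10.0
    onset_jitter: float = 2.0  # onset ~ nominal + U(-jitter, +jitter)
    plume_duration: float = 10.0
    fs_sensor: float = 100.0
    fs_imaging: float = 30.0
    plume_onset: float = 10.0  # actual (jittered) onset for this trial

    def __post_init__(self):
        if self.baseline_end > self.plume_onset:
            raise ValueError("baseline window must end before plume onset")
        if self.plume_onset + self.plume_duration > self.trial_length:
            raise ValueError("plume does not fit inside the trial")

    @property
    def n_sensor(self) -> int:
        return round(self.trial_length * self.fs_sensor)

    @property
    def n_frames(self) -> int:
        return round(self.trial_length * self.fs_imaging)

    def window(self, fs: float, start: float, end: float) -> slice:
        return slice(round(start * fs), round(end * fs))

    def plume_slice(self, fs: float) -> slice:
        return self.window(fs, self.plume_onset, self.plume_onset + self.plume_duration)

    def middle8_slice(self, fs: float) -> slice:
        """Middle 8 s of the 10 s plume (onset+1 s to onset+9 s)."""
        return self.window(fs, self.plume_onset + 1.0, self.plume_onset + 9.0)

    def baseline_slice(self, fs: float) -> slice:
        return self.window(fs, self.baseline_start, self.baseline_end)

    def response_slice(self, fs: float) -> slice:
        """Plume presentation plus 1 s (rebound window) for responsivity."""
        return self.window(
            fs, self.plume_onset, self.plume_onset + self.plume_duration + 1.0
        )


@dataclass(frozen=True)
class GlomerulusSpec:
    """Forward model of one glomerulus's concentration-to-rate transfer.

    rate(t) = sat(tracking_gain * conc(t - response_lag)
              + tonic_gain * plume_on(t)), clipped nonnegative, convolved
    with a GCaMP6f-like double-exponential indicator kernel, frame-averaged
    to the imaging rate, plus Gaussian noise.  ``saturation`` (a.u.) applies
    a soft ceiling sat(x) = s * tanh(x / s); None keeps the transfer linear.
    """

    tracking_gain: float
    tonic_gain: float
    response_lag: float = 0.13
    indicator_tau_rise: float = 0.05
    indicator_tau_decay: float = 0.4
    noise_sd: float = 0.05
    saturation: float | None = 2.5
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.tracking_gain < 0 or self.tonic_gain < 0:
            raise ValueError("gains must be nonnegative")
        if not (self.indicator_tau_decay > self.indicator_tau_rise > 0):
            raise ValueError("indicator requires tau_decay > tau_rise > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def default_glomerulus_population(
    n: int = 20,
    seed: int = 7,
    frame_size: tuple[int, int] | None = None,
) -> list[GlomerulusSpec]:
    """A population spanning the non-tracking to tracking continuum.

    Response strength is log-spaced from weak (lost in noise) to strong, so
    responsivity varies across the population; the tracking share of each
    unit's drive grows with strength (strong responders track best), with
    every fifth unit purely tonic — responsive to odor presence but blind
    to its dynamics.  Response lags jitter around 130 ms.  With
    ``frame_size`` set, circular masks are laid on a grid for movie
    rendering.
    """
    rng = np.random.default_rng(seed)
    specs = []
    strengths = np.geomspace(0.1, 0.5, n)
    for g in range(n):
        frac = g / max(n - 1, 1)
        strength = float(strengths[g])
        tracking = 0.0 if g % 5 == 0 else strength * (0.3 + 0.7 * frac)
        tonic = 0.12 * strength * (0.5 + float(rng.uniform()))
        lag = float(np.clip(rng.normal(0.13, 0.03), 0.03, 0.3))
        mask = None
        if frame_size is not None:
            mask = _circular_mask(frame_size, g, n, rng)
        specs.append(
            GlomerulusSpec(
                tracking_gain=tracking,
                tonic_gain=tonic,
                response_lag=lag,
                noise_sd=0.1,
                mask=mask,
            )
        )
    return specs


def _circular_mask(frame_size, g, n, rng) -> np.ndarray:
    h, w = frame_size
    side = int(np.ceil(np.sqrt(n)))
    cy = (g // side + 0.5) * h / side + rng.uniform(-1, 1)
    cx = (g % side + 0.5) * w / side + rng.uniform(-1, 1)
    radius = 0.30 * min(h, w) / side
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# forward models


def simulate_concentration(
    flow: FlowParams,
    timing: TrialTiming,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trial of plume concentration at the sensor sampling rate.

    Whiff onsets form a Poisson process at ``whiff_rate`` inside the plume
    window; each whiff adds a lognormal amplitude for a lognormal duration.
    The superposition plus background is smoothed by a first-order filter
    with ``fluctuation_timescale`` and is exactly zero outside the window.
    """
    fs = timing.fs_sensor
    n = timing.n_sensor
    conc = np.zeros(n)
    on = timing.plume_onset
    dur = timing.plume_duration

    rate = flow.whiff_rate
    if flow.rate_dispersion is not None:
        # trial-to-trial plume meander: the effective whiff rate at the nose
        # varies across presentations (gamma-mixed Poisson), floored at a
        # quarter of nominal — a released plume rarely misses the sensor
        # entirely at this downwind distance
        rate = max(
            rng.gamma(flow.rate_dispersion, rate / flow.rate_dispersion),
            0.25 * rate,
        )
    n_events = rng.poisson(rate * dur)
    if flow.whiff_rate > 0:
        # a 10 s release always sheds some filaments past the sensor at this
        # downwind distance; only the amount meanders
        n_events = max(n_events, 2)
    starts = on + rng.uniform(0.0, dur, size=n_events)
    lengths = rng.lognormal(flow.whiff_duration_mu, flow.whiff_duration_sigma, n_events)
    amps = rng.lognormal(flow.whiff_amplitude_mu, flow.whiff_amplitude_sigma, n_events)
    for t0, length, amp in zip(starts, lengths, amps):
        i0 = round(t0 * fs)
        i1 = min(round((t0 + length) * fs), n)
        conc[i0:i1] += amp

    window = timing.plume_slice(fs)
    conc[window] += flow.background_mean

    # first-order (exponential) smoothing
    alpha = 1.0 - np.exp(-1.0 / (fs * flow.fluctuation_timescale))
    from scipy.signal import lfilter

    conc = lfilter([alpha], [1.0, alpha - 1.0], conc)

    if flow.noise_sd > 0:
        noise = np.zeros(n)
        seg = noise[window]
        noise[window] = rng.normal(0.0, flow.noise_sd, size=seg.size)
        conc = conc + noise

    mask = np.zeros(n, dtype=bool)
    mask[window] = True
    conc[~mask] = 0.0
    return np.clip(conc, 0.0, None)


def sensor_forward(
    conc: np.ndarray,
    kernel: DeconvKernel,
    noise_sd: float,
    drift_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow MOX sensor reading: (conc * k) + slow drift + white noise."""
    n = conc.size
    y = np.convolve(conc, kernel.values)[:n] * kernel.dt
    if drift_scale > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk -= walk.mean()
        sd = walk.std()
        if sd > 0:
            y = y + drift_scale * walk / sd
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return y


def fluorescence_forward(
    conc: np.ndarray,
    spec: GlomerulusSpec,
    timing: TrialTiming,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """30 Hz fluorescence trace and its ground-truth 30 Hz rate.

    See :class:`GlomerulusSpec` for the transfer model.
    """
    fs = timing.fs_sensor
    n = conc.size
    lag_samples = round(spec.response_lag * fs)
    shifted = np.zeros(n)
    if lag_samples < n:
        shifted[lag_samples:] = conc[: n - lag_samples]
    plume_on = np.zeros(n)
    plume_on[timing.plume_slice(fs)] = 1.0

    rate = spec.tracking_gain * shifted + spec.tonic_gain * plume_on
    if spec.saturation is not None and spec.saturation > 0:
        rate = spec.saturation * np.tanh(rate / spec.saturation)
    rate = np.clip(rate, 0.0, None)

    k_ind = build_kernel(spec.indicator_tau_rise, spec.indicator_tau_decay, fs, n)
    fluor = np.convolve(rate, k_ind.values)[:n] * k_ind.dt

    fluor30 = downsample_to_frames(fluor, fs, timing.fs_imaging)
    rate30 = downsample_to_frames(rate, fs, timing.fs_imaging)
    if spec.noise_sd > 0:
        fluor30 = fluor30 + rng.normal(0.0, spec.noise_sd, size=fluor30.size)
    return fluor30, rate30


def render_movie(
    specs: list[GlomerulusSpec],
    traces: np.ndarray,
    frame_size: tuple[int, int],
    background: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render (T, H, W) frames: sum of mask * trace + background + noise."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] != len(specs):
        raise ValueError("traces must be (n_glomeruli, n_frames)")
    h, w = frame_size
    t = traces.shape[1]
    movie = np.full((t, h, w), float(background))
    for spec, trace in zip(specs, traces):
        if spec.mask is None:
            raise ValueError("every glomerulus needs a mask to render a movie")
        if spec.mask.shape != (h, w):
            raise ValueError("mask does not fit the requested frame size")
        movie[:, spec.mask] += trace[:, None]
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, size=movie.shape)
    return movie


# ---------------------------------------------------------------------------
# session assembly


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 40
    n_medium: int = 10
    block_size: int = 5
    first_block: str = "high"  # condition of the first post-medium block
    timing: TrialTiming = field(default_factory=TrialTiming)
    flow_presets: dict[str, FlowParams] = field(default_factory=default_flow_presets)
    glomeruli: list[GlomerulusSpec] = field(
        default_factory=default_glomerulus_population
    )
    sensor_tau_rise: float = 0.0001
    sensor_tau_decay: float = 0.4629
    sensor_noise_sd: float = 0.002
    sensor_drift_scale: float = 0.05
    reference_noise_sd: float = 0.01
    with_reference: bool = True

    def block_labels(self) -> list[str]:
        """10 medium trials then alternating high/low blocks of five."""
        n_rest = self.n_trials - self.n_medium
        if n_rest < 0 or n_rest % self.block_size != 0:
            raise ValueError(
                "trials after the medium block must fill whole flow blocks"
            )
        if self.first_block not in ("low", "high"):
            raise ValueError("first_block must be 'low' or 'high'")
        other = "low" if self.first_block == "high" else "high"
        labels = ["medium"] * self.n_medium
        for b in range(n_rest // self.block_size):
            labels += [self.first_block if b % 2 == 0 else other] * self.block_size
        return labels


@dataclass
class SessionBundle:
    """All channels of one synthetic session plus ground truth.

    Arrays: conc/sensor/reference are (n_trials, n_sensor_samples) at the
    sensor rate; fluor/truth_rate are (n_trials, n_glomeruli, n_frames) at
    the imaging rate.  ``timings[i]`` carries trial i's jittered onset.
    """

    config: SessionConfig
    seed: int
    flow_labels: list[str]
    timings: list[TrialTiming]
    conc: np.ndarray
    sensor: np.ndarray
    reference: np.ndarray | None
    fluor: np.ndarray
    truth_rate: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.flow_labels)

    @property
    def n_glomeruli(self) -> int:
        return self.fluor.shape[1]

    def trials_in(self, condition: str) -> np.ndarray:
        """Trial indices for 'low'/'medium'/'high' or 'all' (low+high)."""
        if condition == "all":
            return np.array(
                [i for i, lab in enumerate(self.flow_labels) if lab in ("low", "high")]
            )
        return np.array(
            [i for i, lab in enumerate(self.flow_labels) if lab == condition]
        )


def simulate_session(config: SessionConfig, seed: int) -> SessionBundle:
    """Simulate a full session; deterministic in (config, seed)."""
    labels = config.block_labels()
    timing0 = config.timing
    kernel = build_kernel(
        config.sensor_tau_rise, config.sensor_tau_decay,
        timing0.fs_sensor, timing0.n_sensor,
    )
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(len(labels))

    n_glom = len(config.glomeruli)
    conc = np.zeros((len(labels), timing0.n_sensor))
    sensor = np.zeros_like(conc)
    reference = np.zeros_like(conc) if config.with_reference else None
    fluor = np.zeros((len(labels), n_glom, timing0.n_frames))
    truth = np.zeros_like(fluor)
    timings: list[TrialTiming] = []

    for i, (label, tseed) in enumerate(zip(labels, trial_seeds)):
        children = tseed.spawn(3 + n_glom)
        rng_trial = np.random.default_rng(children[0])
        jitter = rng_trial.uniform(-timing0.onset_jitter, timing0.onset_jitter)
        timing = replace(timing0, plume_onset=timing0.nominal_plume_onset + jitter)
        timings.append(timing)

        conc[i] = simulate_concentration(config.flow_presets[label], timing, rng_trial)
        sensor[i] = sensor_forward(
            conc[i], kernel, config.sensor_noise_sd, config.sensor_drift_scale,
            np.random.default_rng(children[1]),
        )
        if reference is not None:
            rng_ref = np.random.default_rng(children[2])
            reference[i] = conc[i] + rng_ref.normal(
                0.0, config.reference_noise_sd, size=conc[i].size
            )
        for g, spec in enumerate(config.glomeruli):
            fluor[i, g], truth[i, g] = fluorescence_forward(
                conc[i], spec, timing, np.random.default_rng(children[3 + g])
            )

    return SessionBundle(
        config=config,
        seed=seed,
        flow_labels=labels,
        timings=timings,
        conc=conc,
        sensor=sensor,
        reference=reference,
        fluor=fluor,
        truth_rate=truth,
    )
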