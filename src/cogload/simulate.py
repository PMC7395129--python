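"""Synthetic multi-subject dual-task sessions with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: an fNIRS optical signal whose cardiac oscillation is frequency
modulated by respiration (respiratory sinus arrhythmia, RSA) and by a latent
cognitive-load variable, with Mayer-wave and drift confounds; EEG background
with frontal blink transients at a load-dependent rate around the resting
norm of ~14/min; a secondary auditory task (beeps answered by pedal press);
and subjective/behavioural targets (NASA-TLX, reaction time, non-response
rate, completion time, error counts) as noisy monotone or U-shaped functions
of load.

Sign structure of the load couplings: load increases HR, decreases RSA depth
(hence HRV) and decreases blink rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "Episode",
    "SessionLayout",
    "LoadEffects",
    "TargetLink",
    "SimulationConfig",
    "OpticalRecording",
    "EEGRecording",
    "SecondaryTaskLog",
    "GroundTruth",
    "SubjectSession",
    "default_layout",
    "simulate_hr_truth",
    "synthesize_fnirs",
    "simulate_blink_times",
    "synthesize_eeg",
    "simulate_behaviour",
    "iter_cohort",
    "simulate_cohort",
    "EEG_CHANNEL_NAMES",
    "FRONTAL_CHANNELS",
    "EXTINCTION",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


TASK_LABELS = ("Task1", "Task2", "Task1R")
REST_LABELS = ("Rest",)
NASA_DIMENSIONS = ("Mental", "Physical", "Temporal", "Performance", "Effort", "Frustration")

#: 19 electrodes of the international 10-20 system.
EEG_CHANNEL_NAMES = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)
FRONTAL_CHANNELS = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")

# Molar extinction coefficients (1/(mM*cm)) for HbO2/HbR at the two
# continuous-wave wavelengths; values in the range tabulated for NIRS work.
EXTINCTION = {
    760.0: {"HbO2": 0.5862, "HbR": 1.5489},
    850.0: {"HbO2": 1.0580, "HbR": 0.6910},
}
DEFAULT_DPF = 6.0


@dataclass(frozen=True)
class Episode:
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start) & (t < self.end)


@dataclass(frozen=True)
class SessionLayout:
    """Ordered, contiguous episode plan for one session."""

    episodes: tuple[Episode, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.episodes]
        if not any(l in TASK_LABELS for l in labels):
            raise ConfigurationError("layout needs at least one task episode")
        if not any(l in REST_LABELS or l == "Baseline" for l in labels):
            raise ConfigurationError("layout needs at least one rest/baseline episode")
        prev_end = None
        for ep in self.episodes:
            if ep.duration <= 0:
                raise ConfigurationError(f"episode {ep.label} has non-positive duration")
            if ep.label in TASK_LABELS and ep.duration > 900:
                raise ConfigurationError("task episodes are capped at 900 s")
            if prev_end is not None and ep.start < prev_end - 1e-9:
                raise ConfigurationError("episodes overlap or are out of order")
            prev_end = ep.end

    @property
    def duration(self) -> float:
        return self.episodes[-1].end

    @property
    def task_episodes(self) -> tuple[Episode, ...]:
        return tuple(e for e in self.episodes if e.label in TASK_LABELS)

    def episode(self, label: str) -> Episode:
        for ep in self.episodes:
            if ep.label == label:
                return ep
        raise KeyError(label)


def default_layout(task_s: float = 300.0, rest_s: float = 120.0, baseline_s: float = 120.0) -> SessionLayout:
    """Baseline, then Task1/Task2/Task1R interleaved with rests.

    Task length defaults to 300 s (the experimental cap is 15 min; desk-scale
    runs use shorter tasks).
    """
    plan = [("Baseline", baseline_s), ("Rest", rest_s), ("Task1", task_s),
            ("Rest", rest_s), ("Task2", task_s), ("Rest", rest_s), ("Task1R", task_s)]
    episodes, t = [], 0.0
    for label, dur in plan:
        episodes.append(Episode(label, t, t + dur))
        t += dur
    return SessionLayout(tuple(episodes))


@dataclass(frozen=True)
class LoadEffects:
    """Effect sizes of the latent load dimensions on physiology.

    Two correlated-in-task but independently varying latents drive the
    session: autonomic *arousal* (effort/stress) and *visual engagement*
    (attention captured by the primary task).  HR and RSA couple to arousal;
    blink suppression couples to engagement.  This two-factor structure is
    what lets blink rate anti-correlate with reaction time while HR does
    too: an aroused subject answers beeps faster (HR up, RT down), a
    visually captured subject blinks less and misses beeps (BR down, RT up).
    """

    hr_bpm: float = 8.0            # bpm per unit arousal
    rsa_depth: float = -0.030      # RSA depth per unit arousal
    blink_per_min: float = -7.5    # blinks/min per unit engagement


@dataclass(frozen=True)
class TargetLink:
    """Link from latent load (or arousal) to one behavioural target."""

    kind: str = "linear"           # "linear" | "quadratic"
    noise_sd: float = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 31
    seed: int = 0
    layout: SessionLayout = field(default_factory=default_layout)
    # cardiac ground truth
    hr_base_mean: float = 70.0     # bpm, across-subject mean
    hr_base_sd: float = 8.0        # bpm, truncated to [45, 100]
    rsa_depth_rest: float = 0.05   # dimensionless FM depth at zero load
    rsa_depth_sd: float = 0.015    # across-subject spread of resting depth
    resp_freq: float = 0.30        # Hz, inside the HF band (0.15-0.8)
    hr_drift_sd: float = 1.0       # bpm slow wander within a session
    hr_lf_amp_bpm: float = 1.0     # Mayer-wave HR modulation (LF band)
    hr_lf_freq: float = 0.1        # Hz
    # fNIRS synthesis
    cardiac_amplitude: float = 1.0  # uM, HbO2 pulse amplitude
    mayer_amplitude: float = 0.4    # uM
    mayer_freq: float = 0.1         # Hz
    drift_sd: float = 0.3           # uM, random-walk scale per sqrt(s)
    noise_sd: float = 0.15          # uM white noise on HbO2
    fnirs_rate: float = 10.0        # Hz
    n_fnirs_channels: int = 8
    wavelengths: tuple[float, float] = (760.0, 850.0)
    source_detector_distance_mm: float = 25.0
    dpf: float = DEFAULT_DPF
    # EEG synthesis
    eeg_rate: float = 2000.0
    n_eeg_channels: int = 19
    eeg_noise_uV: float = 20.0
    blink_amp_uV: float = 120.0
    blink_rate_rest: float = 14.0   # per minute, healthy resting norm
    blink_rate_sd: float = 3.5      # across-subject spread of resting BR
    blink_refractory_s: float = 0.5
    # load model and couplings
    load_effects: LoadEffects = field(default_factory=LoadEffects)
    aptitude_sd: float = 0.30
    episode_load_sd: float = 0.20
    engagement_sd: float = 0.40
    # behaviour
    beep_interval_range: tuple[float, float] = (3.0, 10.0)   # s
    beep_duration_range: tuple[float, float] = (500.0, 1000.0)  # ms
    rt_base_s: float = 0.35
    rt_arousal_slope: float = -0.70   # log RT per unit arousal (faster when keyed up)
    rt_engagement_slope: float = 0.45  # log RT per unit engagement (beeps ignored)
    rt_log_sd: float = 0.20
    miss_intercept: float = -2.5    # logistic non-response model
    miss_arousal_slope: float = -0.8
    miss_engagement_slope: float = 0.8
    target_links: dict[str, TargetLink] = field(default_factory=lambda: {
        "nasa_tlx": TargetLink("linear", 10.0),       # points on the 0-100 scale
        "completion_time": TargetLink("quadratic", 20.0),  # s; Yerkes-Dodson U-shape
        "errors": TargetLink("linear", 0.0),          # Poisson, noise implicit
    })
    completion_base_s: float = 240.0
    completion_quad_gain: float = 150.0
    arousal_optimum: float = 0.8

    def __post_init__(self) -> None:
        for name in ("fnirs_rate", "eeg_rate", "hr_base_mean", "resp_freq"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.15 <= self.resp_freq <= 0.8):
            raise ConfigurationError("resp_freq must lie in the HF band (0.15-0.8 Hz)")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.beep_interval_range[0] <= 0 or self.beep_interval_range[1] < self.beep_interval_range[0]:
            raise ConfigurationError("invalid beep_interval_range")


# ---------------------------------------------------------------------------
# recordings


@dataclass
class OpticalRecording:
    """Multi-channel, dual-wavelength fNIRS optical-density time series."""

    samples: np.ndarray            # (n_series, n_time) optical density, a.u.
    rate: float                    # Hz
    wavelengths: np.ndarray        # nm per series
    channel_pairs: np.ndarray      # optode-pair index per series
    source_detector_distance_mm: float = 25.0
    dpf: float = DEFAULT_DPF
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.rate


@dataclass
class EEGRecording:
    """Multi-channel EEG potentials in microvolts."""

    samples: np.ndarray            # (n_channels, n_time) uV
    rate: float
    channel_names: tuple[str, ...]
    t0: float = 0.0
    bad_channel_mask: np.ndarray | None = None
    removed_fragment_intervals: tuple[tuple[float, float], ...] = ()
    #: original session time of each retained sample after fragment excision
    kept_times: np.ndarray | None = None
    excessive_removal: bool = False

    @property
    def times(self) -> np.ndarray:
        if self.kept_times is not None:
            return self.kept_times
        return self.t0 + np.arange(self.samples.shape[1]) / self.rate


@dataclass
class SecondaryTaskLog:
    """Beep stimuli and pedal responses for one session."""

    stimulus_onsets: np.ndarray    # s
    stimulus_durations: np.ndarray  # ms
    response_times: np.ndarray     # s, NaN where no response


@dataclass
class GroundTruth:
    true_hr: np.ndarray            # bpm on the fNIRS grid, whole session
    true_rsa_depth: dict[str, float]
    true_blink_times: np.ndarray
    true_blink_rate: dict[str, float]
    true_load: dict[str, float]
    true_targets: pd.DataFrame     # noiseless per-task-episode target values
    blink_topography: np.ndarray | None = None


@dataclass
class SubjectSession:
    subject_id: str
    optical: OpticalRecording | None
    eeg: EEGRecording | None
    layout: SessionLayout
    task_log: SecondaryTaskLog
    targets: pd.DataFrame          # one row per task episode
    truth: GroundTruth


# ---------------------------------------------------------------------------
# ground-truth heart rate


def simulate_hr_truth(
    base_hr: float,
    rsa_depth: float,
    resp_freq: float,
    duration: float,
    rng: np.random.Generator,
    rate: float = 10.0,
    drift_sd: float = 0.0,
    phase: float = 0.0,
    lf_amp: float = 0.0,
    lf_freq: float = 0.1,
    lf_phase: float = 0.0,
) -> np.ndarray:
    """Instantaneous heart-rate trajectory (bpm) on a regular grid.

    hr(t) = base + rsa_depth * base * sin(2*pi*resp_freq*t + phase)
                 + lf_amp * sin(2*pi*lf_freq*t + lf_phase) + drift,
    where drift is a smoothed random walk with sd ``drift_sd`` (bpm).  RSA
    makes HR rise during inspiration and fall during expiration; its depth is
    the quantity HRV summarises downstream.  The optional ``lf_amp`` term is
    the Mayer-wave (blood-pressure feedback) modulation of HR near 0.1 Hz —
    it anchors the LF band so the HF/(HF+LF) ratio responds to RSA depth.
    """
    if not (30.0 <= base_hr <= 200.0):
        raise ValueError("base_hr must lie in [30, 200] bpm")
    if rsa_depth < 0:
        raise ValueError("rsa_depth must be >= 0")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    hr = base_hr * (1.0 + rsa_depth * np.sin(2 * np.pi * resp_freq * t + phase))
    if lf_amp:
        hr = hr + lf_amp * np.sin(2 * np.pi * lf_freq * t + lf_phase)
    if drift_sd > 0:
        steps = rng.normal(0.0, 1.0, n)
        walk = np.cumsum(steps)
        # low-pass the walk so the drift stays below the LF band
        from scipy.ndimage import uniform_filter1d

        walk = uniform_filter1d(walk, size=max(int(30 * rate), 1), mode="nearest")
        sd = walk.std()
        if sd > 0:
            hr = hr + drift_sd * (walk - walk.mean()) / sd
    if np.any(hr <= 0):
        raise ValueError("parameters produce non-positive heart rate")
    return hr


# ---------------------------------------------------------------------------
# fNIRS forward model


def _beer_lambert_forward(
    hbo: np.ndarray, hbr: np.ndarray, wavelength: float, distance_mm: float, dpf: float
) -> np.ndarray:
    """Optical-density change produced by concentration changes (uM)."""
    eps = EXTINCTION[wavelength]
    path_cm = distance_mm / 10.0 * dpf
    # concentrations in uM = 1e-3 mM; extinction in 1/(mM cm)
    return (eps["HbO2"] * hbo + eps["HbR"] * hbr) * 1e-3 * path_cm


def synthesize_fnirs(
    true_hr: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> OpticalRecording:
    """Dual-wavelength optical recording carrying the cardiac pulse.

    The HbO2 pulse is a sinusoid whose instantaneous phase is the integral of
    ``true_hr``/60, so beat periods recovered downstream can be compared with
    the generating trajectory.  Mayer-wave (~0.1 Hz) and random-walk drift
    confounds plus white noise are added per channel, then the two wavelength
    series are produced by the forward modified Beer-Lambert mixing.
    """
    rate = config.fnirs_rate
    n = true_hr.size
    t = np.arange(n) / rate
    phase = 2 * np.pi * np.cumsum(true_hr / 60.0) / rate
    n_ch = config.n_fnirs_channels
    series = []
    wavelengths = []
    pairs = []
    for ch in range(n_ch):
        # pulse arrival is near-synchronous across neighbouring optodes;
        # a fully random phase would cancel under channel averaging
        ch_phase = rng.uniform(-0.25, 0.25)
        gain = rng.uniform(0.8, 1.2)
        hbo_cardiac = config.cardiac_amplitude * gain * np.sin(phase + ch_phase)
        hbr_cardiac = -0.25 * hbo_cardiac
        mayer = config.mayer_amplitude * np.sin(
            2 * np.pi * config.mayer_freq * t + rng.uniform(0, 2 * np.pi)
        )
        if config.drift_sd > 0:
            drift = np.cumsum(rng.normal(0.0, config.drift_sd / np.sqrt(rate), n))
        else:
            drift = 0.0
        noise_o = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        noise_r = rng.normal(0.0, config.noise_sd / 2, n) if config.noise_sd > 0 else 0.0
        hbo = hbo_cardiac + mayer + drift + noise_o
        hbr = hbr_cardiac - 0.3 * mayer + noise_r
        for wl in config.wavelengths:
            series.append(_beer_lambert_forward(hbo, hbr, wl, config.source_detector_distance_mm, config.dpf))
            wavelengths.append(wl)
            pairs.append(ch)
    return OpticalRecording(
        samples=np.asarray(series),
        rate=rate,
        wavelengths=np.asarray(wavelengths, dtype=float),
        channel_pairs=np.asarray(pairs),
        source_detector_distance_mm=config.source_detector_distance_mm,
        dpf=config.dpf,
    )


# ---------------------------------------------------------------------------
# blinks and EEG


def simulate_blink_times(
    rate: float,
    duration: float,
    rng: np.random.Generator,
    refractory_s: float = 0.5,
) -> np.ndarray:
    """Blink onset times from a Poisson process with a refractory period.

    Inter-blink intervals are ``refractory + Exp(mean - refractory)`` so the
    expected count stays ``rate * duration / 60``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return np.empty(0)
    mean_gap = 60.0 / rate
    if mean_gap <= refractory_s:
        raise ValueError("rate too high for the refractory period")
    times = []
    t = rng.exponential(mean_gap)
    while t < duration:
        times.append(t)
        t += refractory_s + rng.exponential(mean_gap - refractory_s)
    return np.asarray(times)


def blink_template(rate: float, duration_s: float = 0.30) -> np.ndarray:
    """Stereotyped biphasic blink transient (unit peak amplitude)."""
    n = max(int(round(duration_s * rate)), 3)
    t = np.linspace(0, 1, n)
    lobe = np.sin(np.pi * t) ** 2
    return lobe - 0.25 * np.sin(2 * np.pi * t) * np.sin(np.pi * t)


def blink_topography_for(channel_names: Sequence[str]) -> np.ndarray:
    """Rank-one frontal spatial pattern of the blink artifact (unit max)."""
    weights = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.6, "F8": 0.6, "F3": 0.5,
               "F4": 0.5, "Fz": 0.45, "C3": 0.1, "C4": 0.1, "Cz": 0.1,
               "T7": 0.05, "T8": 0.05}
    return np.asarray([weights.get(name, 0.02) for name in channel_names])


def _pink_noise(n_channels: int, n_samples: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f background via spectral shaping of white noise."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.empty_like(freqs)
    shape[0] = 0.0
    with np.errstate(divide="ignore"):
        shape[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], 0.5))
    white = rng.normal(0.0, 1.0, (n_channels, n_samples))
    spectra = np.fft.rfft(white, axis=1) * shape
    out = np.fft.irfft(spectra, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def synthesize_eeg(
    blink_times: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    duration: float | None = None,
) -> EEGRecording:
    """EEG with 1/f background plus rank-one frontal blink transients.

    The blink artifact is a ~300 ms biphasic pulse broadcast across channels
    through a fixed frontal topography, scaled so it dominates the background
    at frontal electrodes; ICA can therefore isolate it as one component.
    """
    rate = config.eeg_rate
    if duration is None:
        duration = config.layout.duration
    n = int(round(duration * rate))
    names = EEG_CHANNEL_NAMES[: config.n_eeg_channels]
    data = config.eeg_noise_uV * _pink_noise(len(names), n, rate, rng)
    if blink_times.size:
        topo = blink_topography_for(names)
        template = blink_template(rate) * config.blink_amp_uV
        source = np.zeros(n)
        m = template.size
        for bt in blink_times:
            i0 = int(round(bt * rate))
            i1 = min(i0 + m, n)
            if i0 < n:
                source[i0:i1] += template[: i1 - i0]
        data += topo[:, None] * source[None, :]
    return EEGRecording(samples=data, rate=rate, channel_names=tuple(names))


# ---------------------------------------------------------------------------
# behaviour and targets


def _nasa_scores(load: float, noise_sd: float, rng: np.random.Generator) -> dict[str, float]:
    scores = {}
    for dim in NASA_DIMENSIONS:
        raw = 25.0 + 40.0 * load + rng.normal(0.0, noise_sd)
        scores[dim] = float(np.clip(np.round(raw / 5.0) * 5.0, 0.0, 100.0))
    return scores


def simulate_behaviour(
    true_load: dict[str, dict[str, float]],
    layout: SessionLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[SecondaryTaskLog, pd.DataFrame, pd.DataFrame]:
    """Secondary-task log plus noisy and noiseless target tables.

    Beeps run through the Baseline and task episodes with uniform random
    inter-onset gaps.  Each beep is answered after a lognormal latency whose
    log-mean falls with arousal and rises with visual engagement, or missed
    with a logistic probability of the same structure.  A response arriving
    after the next stimulus onset counts as a non-response.  Completion time
    follows a U-shaped (quadratic) function of arousal to emulate a
    Yerkes-Dodson optimum; NASA-TLX dimensions rise linearly with arousal in
    steps of 5; error counts are Poisson with intensity falling in arousal.
    """
    onsets, durations, responses = [], [], []
    beep_lo, beep_hi = config.beep_interval_range
    for ep in layout.episodes:
        if ep.label not in TASK_LABELS and ep.label != "Baseline":
            continue
        a = true_load[ep.label]["arousal"]
        e = true_load[ep.label]["engagement"]
        t = ep.start + rng.uniform(beep_lo, beep_hi)
        ep_onsets = []
        while t < ep.end:
            ep_onsets.append(t)
            t += rng.uniform(beep_lo, beep_hi)
        logit = (config.miss_intercept + config.miss_arousal_slope * a
                 + config.miss_engagement_slope * e)
        p_miss = 1.0 / (1.0 + np.exp(-logit))
        log_mu = (np.log(config.rt_base_s) + config.rt_arousal_slope * a
                  + config.rt_engagement_slope * e)
        for onset in ep_onsets:
            onsets.append(onset)
            durations.append(rng.uniform(*config.beep_duration_range))
            if rng.uniform() < p_miss:
                responses.append(np.nan)
            else:
                responses.append(onset + rng.lognormal(log_mu, config.rt_log_sd))
    log = SecondaryTaskLog(
        stimulus_onsets=np.asarray(onsets),
        stimulus_durations=np.asarray(durations),
        response_times=np.asarray(responses),
    )

    noisy_rows, clean_rows = [], []
    tlx_link = config.target_links.get("nasa_tlx", TargetLink("linear", 10.0))
    ct_link = config.target_links.get("completion_time", TargetLink("quadratic", 20.0))
    for ep in layout.task_episodes:
        a = true_load[ep.label]["arousal"]
        scores = _nasa_scores(a, tlx_link.noise_sd, rng)
        tlx_avg = float(np.mean(list(scores.values())))
        if ct_link.kind == "quadratic":
            ct_clean = config.completion_base_s + config.completion_quad_gain * (
                a - config.arousal_optimum
            ) ** 2
        else:
            ct_clean = config.completion_base_s + config.completion_quad_gain * a
        ct = max(ct_clean + rng.normal(0.0, ct_link.noise_sd), 10.0)
        lam10 = max(1.5 - 0.9 * a, 0.05)
        row = {
            "subject_id": None, "episode_label": ep.label,
            "nasa_tlx_avg": tlx_avg,
            **{f"nasa_{d.lower()}": v for d, v in scores.items()},
            "completion_time": ct,
            "errors_10": int(rng.poisson(lam10)),
            "errors_20": int(rng.poisson(lam10 / 3)),
            "errors_30": int(rng.poisson(lam10 / 6)),
        }
        noisy_rows.append(row)
        clean_rows.append({
            "episode_label": ep.label,
            "nasa_tlx_avg": 25.0 + 40.0 * a,
            "completion_time": ct_clean,
            "errors_10": lam10,
        })
    return log, pd.DataFrame(noisy_rows), pd.DataFrame(clean_rows)


# ---------------------------------------------------------------------------
# cohort


def _episode_loads(
    config: SimulationConfig, aptitude: float, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Latent state per episode label: arousal and visual engagement.

    Rest episodes sit at zero on both axes.  The baseline (secondary task
    alone) is mildly arousing but visually idle, which is why reaction times
    are shortest there.  Task episodes load both axes; repetition lowers
    them.  Arousal inherits the subject's (in)aptitude; engagement varies
    independently across episodes, giving the two factors separable
    signatures downstream.
    """
    base_a = {"Baseline": 0.5, "Rest": 0.0, "Task1": 1.0, "Task2": 1.0, "Task1R": 0.7}
    base_e = {"Baseline": 0.1, "Rest": 0.0, "Task1": 1.0, "Task2": 1.0, "Task1R": 0.8}
    loads: dict[str, dict[str, float]] = {}
    for label in {ep.label for ep in config.layout.episodes}:
        if label in TASK_LABELS:
            a = base_a[label] - aptitude + rng.normal(0.0, config.episode_load_sd)
            e = base_e[label] + rng.normal(0.0, config.engagement_sd)
        elif label == "Baseline":
            a = base_a[label] - 0.5 * aptitude + rng.normal(0.0, config.episode_load_sd / 2)
            e = base_e[label]
        else:
            a, e = 0.0, 0.0
        loads[label] = {"arousal": a, "engagement": e}
    return loads


def simulate_subject(
    config: SimulationConfig,
    subject_id: str,
    rng: np.random.Generator,
    signals: tuple[str, ...] = ("fnirs", "eeg"),
) -> SubjectSession:
    """One subject's full session bundle with ground truth."""
    aptitude = rng.normal(0.0, config.aptitude_sd)
    base_hr = float(np.clip(rng.normal(config.hr_base_mean, config.hr_base_sd), 45.0, 100.0))
    rest_depth = float(np.clip(rng.normal(config.rsa_depth_rest, config.rsa_depth_sd), 0.01, 0.12))
    rest_br = float(np.clip(rng.normal(config.blink_rate_rest, config.blink_rate_sd), 4.0, 30.0))
    loads = _episode_loads(config, aptitude, rng)
    eff = config.load_effects

    # episode-wise HR truth, stitched over the session on the fNIRS grid
    hr_segments = []
    rsa_by_episode: dict[str, float] = {}
    resp_phase = rng.uniform(0, 2 * np.pi)
    lf_phase = rng.uniform(0, 2 * np.pi)
    for ep in config.layout.episodes:
        arousal = loads[ep.label]["arousal"]
        ep_base = float(np.clip(base_hr + eff.hr_bpm * arousal, 35.0, 190.0))
        depth = max(rest_depth + eff.rsa_depth * arousal, 0.004)
        rsa_by_episode[ep.label] = depth
        hr_segments.append(
            simulate_hr_truth(
                ep_base, depth, config.resp_freq, ep.duration, rng,
                rate=config.fnirs_rate, drift_sd=config.hr_drift_sd, phase=resp_phase,
                lf_amp=config.hr_lf_amp_bpm, lf_freq=config.hr_lf_freq, lf_phase=lf_phase,
            )
        )
        resp_phase += 2 * np.pi * config.resp_freq * ep.duration
        lf_phase += 2 * np.pi * config.hr_lf_freq * ep.duration
    true_hr = np.concatenate(hr_segments)

    optical = synthesize_fnirs(true_hr, config, rng) if "fnirs" in signals else None

    # blink ground truth per episode, stitched into one session-long series
    blink_rate_by_episode: dict[str, float] = {}
    blink_times = []
    for ep in config.layout.episodes:
        br = max(rest_br + eff.blink_per_min * loads[ep.label]["engagement"], 0.5)
        blink_rate_by_episode[ep.label] = br
        times = simulate_blink_times(br, ep.duration, rng, config.blink_refractory_s)
        blink_times.append(times + ep.start)
    blink_times = np.concatenate(blink_times) if blink_times else np.empty(0)

    eeg = synthesize_eeg(blink_times, config, rng) if "eeg" in signals else None

    log, targets, clean_targets = simulate_behaviour(loads, config.layout, config, rng)
    targets["subject_id"] = subject_id

    truth = GroundTruth(
        true_hr=true_hr,
        true_rsa_depth=rsa_by_episode,
        true_blink_times=blink_times,
        true_blink_rate=blink_rate_by_episode,
        true_load=loads,
        true_targets=clean_targets,
        blink_topography=blink_topography_for(EEG_CHANNEL_NAMES[: config.n_eeg_channels]),
    )
    return SubjectSession(
        subject_id=subject_id, optical=optical, eeg=eeg, layout=config.layout,
        task_log=log, targets=targets, truth=truth,
    )


def iter_cohort(
    config: SimulationConfig,
    signals: tuple[str, ...] = ("fnirs", "eeg"),
) -> Iterator[SubjectSession]:
    """Lazily generate subject bundles (deterministic given config.seed)."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    for i, ss in enumerate(seeds):
        yield simulate_subject(config, f"S{i + 1:02d}", np.random.default_rng(ss), signals)


def simulate_cohort(
    config: SimulationConfig,
    signals: tuple[str, ...] = ("fnirs", "eeg"),
) -> list[SubjectSession]:
    """Materialised cohort; prefer :func:`iter_cohort` for large sessions."""
    return list(iter_cohort(config, signals))
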