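"""Blink detection from EEG: cleaning, ICA, component selection, peak picking.

The chain mirrors standard artifact-oriented EEG pre-processing: per-episode
baseline correction, excision of 1 s fragments exceeding +/-200 uV, rejection
of channels with sample kurtosis above 5, zero-phase Hamming windowed-sinc
FIR band-pass (0.16-40 Hz), downsampling to 200 Hz, ICA decomposition, and
selection of blink components by a frontal-dominance + source-kurtosis
heuristic (a deliberately simple stand-in for full artifact classifiers such
as ADJUST).  Blink times are the sharp peaks of the selected component;
blink rate is events per minute of effective (non-excised) episode time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from .simulate import EEGRecording, FRONTAL_CHANNELS

__all__ = [
    "ComponentSet",
    "BlinkEvents",
    "baseline_correct",
    "clean_eeg",
    "filter_downsample_eeg",
    "decompose_ica",
    "identify_blink_components",
    "detect_blink_events",
    "blink_rate",
    "blinks_from_eeg",
]


@dataclass
class ComponentSet:
    """ICA decomposition: sources = unmixing @ (data - mean)."""

    unmixing: np.ndarray           # (k, n_channels)
    sources: np.ndarray            # (k, n_time)
    topographies: np.ndarray       # (n_channels, k)
    mean: np.ndarray               # per-channel mean removed before unmixing
    rate: float
    channel_names: tuple[str, ...]
    t0: float = 0.0
    #: original session time per sample (survives fragment excision)
    sample_times: np.ndarray | None = None


@dataclass
class BlinkEvents:
    times: np.ndarray              # s, strictly increasing
    source_component: int
    scores: dict | None = None


def baseline_correct(eeg: EEGRecording, episodes) -> EEGRecording:
    """Subtract the within-episode mean from every channel (epoch baseline)."""
    out = eeg.samples.copy()
    t = eeg.times
    for ep in episodes:
        sel = ep.contains(t)
        if np.any(sel):
            out[:, sel] -= out[:, sel].mean(axis=1, keepdims=True)
    return replace(eeg, samples=out)


def clean_eeg(
    eeg: EEGRecording,
    amp_thresh_uV: float = 200.0,
    window_ms: float = 1000.0,
    kurt_thresh: float = 5.0,
) -> EEGRecording:
    """Excise high-amplitude fragments and reject high-kurtosis channels.

    The record is scanned in non-overlapping windows of ``window_ms``; any
    window in which any channel exceeds ``amp_thresh_uV`` in magnitude is
    removed from all channels (the interval is logged).  Channels whose
    sample kurtosis (Fisher) exceeds ``kurt_thresh`` are masked out.
    Raises if every channel is rejected; a flag warns when more than half the
    record is excised.
    """
    n_ch, n = eeg.samples.shape
    win = max(int(round(window_ms / 1000.0 * eeg.rate)), 1)
    n_win = int(np.ceil(n / win))
    keep = np.ones(n, dtype=bool)
    removed = []
    for w in range(n_win):
        i0, i1 = w * win, min((w + 1) * win, n)
        if np.any(np.abs(eeg.samples[:, i0:i1]) > amp_thresh_uV):
            keep[i0:i1] = False
            removed.append((eeg.t0 + i0 / eeg.rate, eeg.t0 + i1 / eeg.rate))
    data = eeg.samples[:, keep]
    kurt = stats.kurtosis(data, axis=1, fisher=True, bias=True)
    bad = kurt > kurt_thresh
    if np.all(bad):
        raise ValueError("all channels rejected by the kurtosis criterion")
    times = eeg.t0 + np.arange(n) / eeg.rate
    return replace(
        eeg,
        samples=data,
        bad_channel_mask=bad,
        removed_fragment_intervals=tuple(removed),
        kept_times=times[keep],
        excessive_removal=bool((~keep).sum() > 0.5 * n),
    )


def _fir_taps(rate: float, band: tuple[float, float], n_samples: int) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps; length set by the low edge."""
    lo, hi = band
    trans_lo = lo                          # transition width at the low edge
    numtaps = int(np.ceil(3.3 / (trans_lo / rate)))
    max_taps = max((n_samples // 3) * 2 - 1, 11)
    numtaps = min(numtaps, max_taps)
    if numtaps % 2 == 0:
        numtaps += 1
    hi_cut = min(hi + 2.5, 0.98 * rate / 2)
    taps = signal.firwin(numtaps, [lo, hi_cut], pass_zero=False, window="hamming", fs=rate)
    # exact null at DC even when the record caps the kernel length
    return taps - taps.mean()


def filter_downsample_eeg(
    eeg: EEGRecording,
    band: tuple[float, float] = (0.16, 40.0),
    out_rate: float = 200.0,
) -> EEGRecording:
    """Zero-phase FIR band-pass then decimation.

    The symmetric (linear-phase) windowed-sinc kernel is applied by 'same'
    convolution, which is exactly zero-phase.  The 40 Hz cut-off anti-aliases
    the subsequent decimation to 200 Hz.
    """
    if out_rate > eeg.rate:
        raise ValueError("out_rate must not exceed the input rate")
    if eeg.rate < 2 * band[1]:
        raise ValueError("input rate below twice the upper band edge")
    taps = _fir_taps(eeg.rate, band, eeg.samples.shape[1])
    demeaned = eeg.samples - eeg.samples.mean(axis=1, keepdims=True)
    filtered = signal.fftconvolve(demeaned, taps[None, :], mode="same", axes=1)
    factor = eeg.rate / out_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("input rate must be an integer multiple of out_rate")
    factor = int(round(factor))
    ds = filtered[:, ::factor]
    kept = eeg.kept_times[::factor] if eeg.kept_times is not None else None
    return replace(eeg, samples=ds, rate=out_rate, kept_times=kept)


def decompose_ica(
    eeg: EEGRecording,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
) -> ComponentSet:
    """ICA of the retained channels (deterministic given ``seed``).

    The contract is algorithm-agnostic: any full-rank unmixing whose sources
    reconstruct the data serves; FastICA is the backend here.
    """
    mask = eeg.bad_channel_mask
    if mask is None:
        mask = np.zeros(eeg.samples.shape[0], dtype=bool)
    data = eeg.samples[~mask]
    names = tuple(np.asarray(eeg.channel_names)[~mask])
    n_ch = data.shape[0]
    if n_components is None:
        n_components = n_ch
    if np.linalg.matrix_rank(data @ data.T) < n_components:
        raise ValueError(
            "rank-deficient data: reduce n_components or drop duplicated channels"
        )
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=max_iter, whiten="unit-variance")
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # near-Gaussian background components stall FastICA's fixed point;
        # the blink component converges long before max_iter
        _warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(data.T).T
    unmixing = ica.components_
    topographies = ica.mixing_
    return ComponentSet(
        unmixing=unmixing,
        sources=sources,
        topographies=topographies,
        mean=ica.mean_,
        rate=eeg.rate,
        channel_names=names,
        t0=eeg.t0,
        sample_times=eeg.kept_times,
    )


def component_scores(cs: ComponentSet, frontal_channels=FRONTAL_CHANNELS) -> list[dict]:
    """Frontal-dominance ratio and source kurtosis per component."""
    frontal = np.isin(np.asarray(cs.channel_names), list(frontal_channels))
    scores = []
    for k in range(cs.sources.shape[0]):
        topo = np.abs(cs.topographies[:, k])
        total = topo.sum()
        ratio = float(topo[frontal].sum() / total) if total > 0 else 0.0
        kurt = float(stats.kurtosis(cs.sources[k], fisher=True, bias=True))
        scores.append({"component": k, "frontal_ratio": ratio, "kurtosis": kurt})
    return scores


def identify_blink_components(
    cs: ComponentSet,
    frontal_channels=FRONTAL_CHANNELS,
    frontal_ratio_thresh: float = 0.6,
    kurt_thresh: float = 5.0,
) -> list[int]:
    """Flag components that are both frontally dominant and spiky.

    A blink component projects almost exclusively to frontal electrodes and
    its time course is sparse (high kurtosis).  Both criteria must hold; an
    empty result is valid and marks the blink rate undefined downstream.
    """
    flagged = []
    for s in component_scores(cs, frontal_channels):
        if s["frontal_ratio"] >= frontal_ratio_thresh and s["kurtosis"] >= kurt_thresh:
            flagged.append(s["component"])
    return flagged


def detect_blink_events(
    cs: ComponentSet,
    flagged: list[int],
    min_separation_s: float = 0.2,
    mad_k: float = 8.0,
    smooth_s: float = 0.1,
) -> BlinkEvents | None:
    """Sharp-peak detection on the best flagged source.

    The source with the highest kurtosis among the flagged set is polarity
    aligned (blink deflections made positive via the skewness sign) and
    smoothed by a ``smooth_s`` moving average (the blink timescale), which
    suppresses sample-level noise excursions.  Local maxima above
    ``median + mad_k * MAD`` and at least ``min_separation_s`` apart are
    taken as blink times.  The default ``mad_k = 8`` sits above the expected
    maximum of the smoothed background over multi-minute records while blink
    deflections land an order of magnitude higher.  Returns ``None`` when
    the flagged set is empty (undefined marker).
    """
    if not flagged:
        return None
    kurts = {k: stats.kurtosis(cs.sources[k], bias=True) for k in flagged}
    best = max(kurts, key=kurts.get)
    src = cs.sources[best].astype(float)
    skew = stats.skew(src)
    if skew < 0:
        src = -src
    w = max(int(round(smooth_s * cs.rate)), 1)
    if w > 1:
        src = np.convolve(src, np.ones(w) / w, mode="same")
    mad = stats.median_abs_deviation(src)
    thresh = np.median(src) + mad_k * (mad if mad > 0 else src.std() / 1.4826 or 1.0)
    distance = max(int(round(min_separation_s * cs.rate)), 1)
    peaks, _ = signal.find_peaks(src, height=thresh, distance=distance)
    if cs.sample_times is not None:
        times = cs.sample_times[peaks]
    else:
        times = cs.t0 + peaks / cs.rate
    return BlinkEvents(times=times, source_component=best)


def blink_rate(
    events: BlinkEvents | None,
    episode: tuple[float, float],
    removed_fragments=(),
) -> float:
    """Events per minute of effective episode duration.

    Excised fragments overlapping the episode are subtracted from the
    duration.  NaN when events are undefined or effective duration is zero.
    """
    if events is None:
        return float("nan")
    start, end = episode
    effective = end - start
    for f0, f1 in removed_fragments:
        effective -= max(0.0, min(end, f1) - max(start, f0))
    if effective <= 0:
        return float("nan")
    count = int(np.sum((events.times >= start) & (events.times < end)))
    return 60.0 * count / effective


def blinks_from_eeg(
    eeg: EEGRecording,
    episodes,
    seed: int = 0,
    n_components: int | None = None,
    **select_kwargs,
) -> tuple[BlinkEvents | None, EEGRecording]:
    """Convenience chain: baseline-correct, clean, filter, ICA, detect.

    Returns the events (or ``None``) and the cleaned recording, whose
    ``removed_fragment_intervals`` feed effective-duration normalisation.
    """
    corrected = baseline_correct(eeg, episodes)
    cleaned = clean_eeg(corrected)
    filtered = filter_downsample_eeg(cleaned)
    cs = decompose_ica(filtered, n_components=n_components, seed=seed)
    flagged = identify_blink_components(cs, **select_kwargs)
    events = detect_blink_events(cs, flagged)
    return events, cleaned
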