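"""Heart rate and spectral HRV from the cardiac pulse in fNIRS optical signals.

Pipeline: modified Beer-Lambert conversion of dual-wavelength optical-density
changes to oxy-hemoglobin concentration, zero-phase 0.5-2 Hz band-pass,
channel averaging, beat-period detection from zero crossings (the interval
between every other crossing is one beat), instantaneous HR = 60/period
interpolated onto the regular fNIRS grid, and a band-ratio HRV statistic

    HRV = HF / (HF + LF),  LF: 0.01-0.15 Hz,  HF: 0.15-0.8 Hz,

computed from the power spectral density of HR segments.  HRV in [0, 1]
measures how strongly the heart rate is modulated by respiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import EXTINCTION, OpticalRecording

__all__ = [
    "HemoglobinSeries",
    "BeatSeries",
    "HeartRateSeries",
    "BandPowers",
    "HRVSeries",
    "LF_BAND",
    "HF_BAND",
    "convert_beer_lambert",
    "extract_cardiac_waveform",
    "detect_beat_periods",
    "heart_rate_series",
    "compute_band_powers",
    "compute_hrv",
    "compute_hrv_series",
    "hr_hrv_from_optical",
]

LF_BAND = (0.01, 0.15)
HF_BAND = (0.15, 0.8)
CARDIAC_BAND = (0.5, 2.0)
#: plausibility gate on beat periods, mirroring the 0.5-2 Hz design band
PERIOD_GATE_S = (0.3, 2.0)


@dataclass
class HemoglobinSeries:
    """Oxy-hemoglobin concentration change per optode pair (uM)."""

    oxy: np.ndarray                # (n_pairs, n_time)
    rate: float
    deoxy: np.ndarray | None = None


@dataclass
class BeatSeries:
    """Beat midpoint times and periods from zero-crossing detection."""

    beat_mid_times: np.ndarray     # s
    periods: np.ndarray            # s
    flagged_empty: bool = False


@dataclass
class HeartRateSeries:
    t: np.ndarray                  # regular grid, s
    hr: np.ndarray                 # bpm
    rate: float


@dataclass
class BandPowers:
    lf: float                      # bpm^2 in 0.01-0.15 Hz
    hf: float                      # bpm^2 in 0.15-0.8 Hz


@dataclass
class HRVSeries:
    t: np.ndarray                  # window-centre times, s
    hrv: np.ndarray                # dimensionless, in [0, 1] where defined


def convert_beer_lambert(
    optical: OpticalRecording,
    extinction_table: dict | None = None,
    dpf: float | None = None,
    distance_mm: float | None = None,
) -> HemoglobinSeries:
    """Invert the modified Beer-Lambert law per optode pair.

    For each pair the optical-density changes at the two wavelengths form a
    2x2 linear system in (dHbO2, dHbR); it is solved per sample.  The result
    is in uM given extinction coefficients in 1/(mM*cm) and the optical path
    ``distance * DPF``.
    """
    table = extinction_table if extinction_table is not None else EXTINCTION
    dpf = dpf if dpf is not None else optical.dpf
    distance_mm = distance_mm if distance_mm is not None else optical.source_detector_distance_mm
    if distance_mm <= 0:
        raise ValueError("source-detector distance must be > 0")
    pairs = np.unique(optical.channel_pairs)
    oxy_rows, deoxy_rows = [], []
    path_cm = distance_mm / 10.0 * dpf
    for pair in pairs:
        idx = np.flatnonzero(optical.channel_pairs == pair)
        wls = optical.wavelengths[idx]
        if np.unique(wls).size < 2:
            raise ValueError(f"optode pair {pair} lacks two distinct wavelengths")
        E = np.array([[table[wl]["HbO2"], table[wl]["HbR"]] for wl in wls])
        if abs(np.linalg.det(E)) < 1e-12:
            raise ValueError("singular extinction matrix")
        od = optical.samples[idx] / (1e-3 * path_cm)   # back to mM*extinction units, then uM
        conc = np.linalg.solve(E, od)
        oxy_rows.append(conc[0])
        deoxy_rows.append(conc[1])
    return HemoglobinSeries(oxy=np.asarray(oxy_rows), rate=optical.rate, deoxy=np.asarray(deoxy_rows))


def _bandpass_sos(rate: float, band: tuple[float, float] = CARDIAC_BAND, order: int = 4):
    nyq = rate / 2.0
    lo, hi = band
    hi = min(hi, 0.95 * nyq)
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def extract_cardiac_waveform(hemo: HemoglobinSeries, band: tuple[float, float] = CARDIAC_BAND) -> np.ndarray:
    """Zero-phase band-pass (Butterworth order 4) then channel average.

    Operates on the oxy-hemoglobin series; the output is zero-mean and
    carries the cardiac oscillation.
    """
    n = hemo.oxy.shape[1]
    if n < 10 * hemo.rate:
        raise ValueError("record shorter than 10 s: filter warm-up not satisfied")
    sos = _bandpass_sos(hemo.rate, band)
    filtered = signal.sosfiltfilt(sos, hemo.oxy, axis=1)
    out = filtered.mean(axis=0)
    return out - out.mean()


def detect_beat_periods(cardiac: np.ndarray, rate: float, t0: float = 0.0) -> BeatSeries:
    """Beat periods as intervals between every other zero-crossing.

    Crossing times are refined by linear interpolation between the bracketing
    samples.  Successive crossings alternate direction, so the interval from
    crossing ``i`` to ``i+2`` spans one full cycle; its midpoint timestamps
    the beat.  Periods outside the plausibility gate [0.3, 2.0] s are
    discarded.
    """
    x = np.asarray(cardiac, dtype=float)
    s = np.sign(x)
    s[s == 0] = 1.0
    idx = np.flatnonzero(np.diff(s) != 0)
    if idx.size < 3:
        return BeatSeries(np.empty(0), np.empty(0), flagged_empty=True)
    frac = x[idx] / (x[idx] - x[idx + 1])
    t_cross = (idx + frac) / rate + t0
    periods = t_cross[2:] - t_cross[:-2]
    mids = 0.5 * (t_cross[2:] + t_cross[:-2])
    ok = (periods >= PERIOD_GATE_S[0]) & (periods <= PERIOD_GATE_S[1])
    return BeatSeries(mids[ok], periods[ok], flagged_empty=not np.any(ok))


def heart_rate_series(
    beats: BeatSeries,
    grid: np.ndarray | None = None,
    rate: float = 10.0,
    t0: float = 0.0,
    duration: float | None = None,
) -> HeartRateSeries:
    """HR = 60/period at beat midpoints, linearly interpolated onto the grid.

    Values beyond the first/last beat are constant-extrapolated.
    """
    if beats.periods.size < 2:
        raise ValueError("need at least two beats to interpolate a heart-rate series")
    if grid is None:
        if duration is None:
            duration = beats.beat_mid_times[-1]
        grid = t0 + np.arange(int(round(duration * rate))) / rate
    hr_beats = 60.0 / beats.periods
    hr = np.interp(grid, beats.beat_mid_times, hr_beats)
    step = float(np.median(np.diff(grid))) if grid.size > 1 else 1.0 / rate
    return HeartRateSeries(t=grid, hr=hr, rate=1.0 / step)


def compute_band_powers(
    hr: np.ndarray,
    rate: float,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    window: str = "hann",
    estimator: str = "periodogram",
) -> BandPowers:
    """LF and HF band powers of a detrended HR segment.

    Power spectral density by Hann-tapered periodogram (Welch selectable),
    integrated over each band.  Bins below the segment's frequency resolution
    cannot be attributed to a band and are excluded; a segment shorter than
    10 s cannot resolve the HF band and raises.
    """
    x = np.asarray(hr, dtype=float)
    n = x.size
    if n / rate < 10.0:
        raise ValueError("segment too short to resolve the HF band (need >= 10 s)")
    x = x - x.mean()
    if estimator == "welch":
        nper = min(n, max(int(rate * 60), 256))
        f, pxx = signal.welch(x, fs=rate, window=window, nperseg=nper)
    else:
        f, pxx = signal.periodogram(x, fs=rate, window=window)
    df = f[1] - f[0]
    resolvable = f >= df - 1e-12

    def band_power(lo: float, hi: float) -> float:
        sel = resolvable & (f >= lo) & (f < hi)
        return float(np.sum(pxx[sel]) * df)

    return BandPowers(lf=band_power(*lf_band), hf=band_power(*hf_band))


def compute_hrv(bp: BandPowers) -> float:
    """HRV = HF / (HF + LF); NaN when total band power is zero."""
    total = bp.lf + bp.hf
    if total <= 0 or not np.isfinite(total):
        return float("nan")
    return bp.hf / total


def compute_hrv_series(
    hr: HeartRateSeries,
    window_s: float = 30.0,
    step_s: float = 1.0,
    estimator: str = "periodogram",
) -> HRVSeries:
    """Sliding-window HRV time course with window-centre timestamps."""
    n = hr.hr.size
    win = int(round(window_s * hr.rate))
    step = max(int(round(step_s * hr.rate)), 1)
    if win > n:
        raise ValueError("window longer than the record")
    starts = np.arange(0, n - win + 1, step)
    t_out = hr.t[starts] + window_s / 2.0
    vals = np.empty(starts.size)
    for j, s0 in enumerate(starts):
        bp = compute_band_powers(hr.hr[s0 : s0 + win], hr.rate, estimator=estimator)
        vals[j] = compute_hrv(bp)
    return HRVSeries(t=t_out, hrv=vals)


def hr_hrv_from_optical(
    optical: OpticalRecording,
    hrv_window_s: float = 30.0,
    hrv_step_s: float = 1.0,
) -> tuple[HeartRateSeries, HRVSeries]:
    """Convenience chain: Beer-Lambert -> band-pass -> beats -> HR -> HRV."""
    hemo = convert_beer_lambert(optical)
    cardiac = extract_cardiac_waveform(hemo)
    beats = detect_beat_periods(cardiac, optical.rate, t0=optical.t0)
    n = optical.samples.shape[1]
    grid = optical.t0 + np.arange(n) / optical.rate
    hr = heart_rate_series(beats, grid=grid)
    hrv = compute_hrv_series(hr, window_s=hrv_window_s, step_s=hrv_step_s)
    return hr, hrv
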