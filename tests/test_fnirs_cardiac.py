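"""HR/HRV extraction: Beer-Lambert algebra, beats, band powers, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from cogload import fnirs_cardiac as fc
from cogload import simulate
from cogload.simulate import EXTINCTION, OpticalRecording, SimulationConfig


def _make_optical(hbo, hbr, rate=10.0, distance=25.0, dpf=6.0):
    """Forward-mix known concentrations into a dual-wavelength recording."""
    rows, wls, pairs = [], [], []
    path_cm = distance / 10.0 * dpf
    for wl in (760.0, 850.0):
        eps = EXTINCTION[wl]
        rows.append((eps["HbO2"] * hbo + eps["HbR"] * hbr) * 1e-3 * path_cm)
        wls.append(wl)
        pairs.append(0)
    return OpticalRecording(
        samples=np.asarray(rows), rate=rate, wavelengths=np.asarray(wls),
        channel_pairs=np.asarray(pairs), source_detector_distance_mm=distance, dpf=dpf,
    )


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self):
        rec = _make_optical(np.zeros(100), np.zeros(100))
        hemo = fc.convert_beer_lambert(rec)
        assert np.allclose(hemo.oxy, 0.0)

    def test_algebraic_round_trip(self, rng):
        hbo = rng.normal(size=500)
        hbr = rng.normal(size=500)
        hemo = fc.convert_beer_lambert(_make_optical(hbo, hbr))
        assert np.allclose(hemo.oxy[0], hbo, rtol=1e-9, atol=1e-12)
        assert np.allclose(hemo.deoxy[0], hbr, rtol=1e-9, atol=1e-12)

    def test_linearity_in_optical_density(self, rng):
        hbo, hbr = rng.normal(size=200), rng.normal(size=200)
        rec = _make_optical(hbo, hbr)
        scaled = OpticalRecording(
            samples=3.0 * rec.samples, rate=rec.rate, wavelengths=rec.wavelengths,
            channel_pairs=rec.channel_pairs,
            source_detector_distance_mm=rec.source_detector_distance_mm, dpf=rec.dpf,
        )
        assert np.allclose(fc.convert_beer_lambert(scaled).oxy, 3.0 * fc.convert_beer_lambert(rec).oxy)

    def test_single_wavelength_rejected(self):
        rec = _make_optical(np.zeros(50), np.zeros(50))
        rec.wavelengths[:] = 760.0
        with pytest.raises(ValueError, match="wavelength"):
            fc.convert_beer_lambert(rec)


class TestCardiacWaveform:
    def test_passband_and_stopband(self):
        t = np.arange(0, 120, 0.1)
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 0.1 * t)
        hemo = fc.HemoglobinSeries(oxy=x[None, :], rate=10.0)
        out = fc.extract_cardiac_waveform(hemo)
        f, pxx = signal.periodogram(out, fs=10.0)
        p_1hz = pxx[np.argmin(np.abs(f - 1.0))]
        p_01hz = pxx[np.argmin(np.abs(f - 0.1))]
        assert 10 * np.log10(p_1hz / p_01hz) >= 20.0

    def test_constant_input_gives_zero(self):
        hemo = fc.HemoglobinSeries(oxy=np.full((2, 200), 5.0), rate=10.0)
        assert np.allclose(fc.extract_cardiac_waveform(hemo), 0.0, atol=1e-8)

    def test_channel_permutation_invariance(self, rng):
        x = rng.normal(size=(4, 300))
        a = fc.extract_cardiac_waveform(fc.HemoglobinSeries(oxy=x, rate=10.0))
        b = fc.extract_cardiac_waveform(fc.HemoglobinSeries(oxy=x[::-1], rate=10.0))
        assert np.allclose(a, b)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            fc.extract_cardiac_waveform(fc.HemoglobinSeries(oxy=np.zeros((1, 50)), rate=10.0))


class TestBeatDetection:
    @pytest.mark.parametrize("freq,expected_hr", [(1.0, 60.0), (1.2, 72.0)])
    def test_pure_tone_periods(self, freq, expected_hr):
        t = np.arange(0, 60, 0.1)
        beats = fc.detect_beat_periods(np.sin(2 * np.pi * freq * t), 10.0)
        assert beats.periods.size > 50
        assert np.allclose(beats.periods, 1.0 / freq, atol=0.1)
        assert np.allclose(60.0 / np.median(beats.periods), expected_hr, atol=1.0)

    def test_chirp_tracks_instantaneous_frequency(self):
        rate, dur = 10.0, 60.0
        t = np.arange(0, dur, 1 / rate)
        f0, f1 = 0.8, 1.5
        x = signal.chirp(t, f0=f0, t1=dur, f1=f1, method="linear")
        beats = fc.detect_beat_periods(x, rate)
        f_inst_true = f0 + (f1 - f0) * beats.beat_mid_times / dur
        f_inst_est = 1.0 / beats.periods
        rel = np.abs(f_inst_est - f_inst_true) / f_inst_true
        assert np.median(rel) < 0.02

    def test_too_few_crossings_flagged(self):
        beats = fc.detect_beat_periods(np.ones(100), 10.0)
        assert beats.flagged_empty
        assert beats.periods.size == 0

    def test_out_of_gate_periods_discarded(self):
        t = np.arange(0, 60, 0.1)
        beats = fc.detect_beat_periods(np.sin(2 * np.pi * 0.1 * t), 10.0)  # 10 s period
        assert beats.periods.size == 0


class TestHeartRateSeries:
    def test_constant_periods_flat_series(self):
        beats = fc.BeatSeries(np.arange(10, 60, 1.0), np.ones(50))
        hr = fc.heart_rate_series(beats, grid=np.arange(0, 60, 0.1))
        assert np.allclose(hr.hr, 60.0)

    def test_midpoint_linear_interpolation(self):
        beats = fc.BeatSeries(np.array([10.0, 20.0]), np.array([1.0, 0.5]))
        hr = fc.heart_rate_series(beats, grid=np.array([15.0]))
        assert hr.hr[0] == pytest.approx(90.0)

    def test_constant_extrapolation_at_edges(self):
        beats = fc.BeatSeries(np.array([10.0, 20.0]), np.array([1.0, 0.5]))
        hr = fc.heart_rate_series(beats, grid=np.array([0.0, 30.0]))
        assert hr.hr[0] == pytest.approx(60.0)
        assert hr.hr[1] == pytest.approx(120.0)

    def test_empty_beats_rejected(self):
        with pytest.raises(ValueError):
            fc.heart_rate_series(fc.BeatSeries(np.empty(0), np.empty(0)))


class TestBandPowersAndHRV:
    def test_hf_dominates_for_resp_band_modulation(self):
        t = np.arange(0, 60, 0.1)
        bp = fc.compute_band_powers(70 + np.sin(2 * np.pi * 0.3 * t), 10.0)
        assert bp.hf / max(bp.lf, 1e-30) > 100

    def test_lf_dominates_for_slow_modulation(self):
        t = np.arange(0, 120, 0.1)
        bp = fc.compute_band_powers(70 + np.sin(2 * np.pi * 0.05 * t), 10.0)
        assert bp.lf / max(bp.hf, 1e-30) > 100

    def test_constant_hr_zero_power(self):
        bp = fc.compute_band_powers(np.full(600, 70.0), 10.0)
        assert bp.lf == pytest.approx(0.0, abs=1e-20)
        assert bp.hf == pytest.approx(0.0, abs=1e-20)

    def test_band_powers_match_dft_oracle(self, rng):
        # independent oracle: rectangular-window DFT with explicit bin sum
        for _ in range(50):
            x = rng.normal(size=300)
            bp = fc.compute_band_powers(x, 10.0, window="boxcar")
            xc = x - x.mean()
            n = xc.size
            spec = np.abs(np.fft.rfft(xc)) ** 2 / (n * 10.0)
            spec[1:-1] *= 2.0
            f = np.fft.rfftfreq(n, 0.1)
            df = f[1] - f[0]
            lf = spec[(f >= 0.01) & (f < 0.15) & (f >= df - 1e-12)].sum() * df
            hf = spec[(f >= 0.15) & (f < 0.8)].sum() * df
            assert bp.lf == pytest.approx(lf, rel=1e-8, abs=1e-12)
            assert bp.hf == pytest.approx(hf, rel=1e-8, abs=1e-12)

    @pytest.mark.parametrize("lf,hf,expected", [(0.0, 5.0, 1.0), (5.0, 0.0, 0.0), (3.0, 3.0, 0.5)])
    def test_hrv_ratio_examples(self, lf, hf, expected):
        assert fc.compute_hrv(fc.BandPowers(lf=lf, hf=hf)) == pytest.approx(expected)

    def test_hrv_undefined_for_zero_power(self):
        assert np.isnan(fc.compute_hrv(fc.BandPowers(0.0, 0.0)))

    @given(lf=st.floats(0.0, 1e6), hf=st.floats(0.0, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_hrv_bounded_and_monotone_in_hf(self, lf, hf):
        v = fc.compute_hrv(fc.BandPowers(lf, hf))
        if lf + hf > 0:
            assert 0.0 <= v <= 1.0
            v2 = fc.compute_hrv(fc.BandPowers(lf, hf + 1.0))
            assert v2 >= v
            if 1e-6 < v < 1.0 - 1e-6:
                assert v2 > v


class TestHRVSeries:
    def test_window_count(self):
        hr = fc.HeartRateSeries(t=np.arange(0, 120, 0.1), hr=70 + np.sin(np.arange(1200) * 0.2), rate=10.0)
        out = fc.compute_hrv_series(hr, window_s=30.0, step_s=5.0)
        assert out.t.size == int((120 - 30) / 5) + 1

    def test_pure_hf_modulation_high_everywhere(self):
        t = np.arange(0, 120, 0.1)
        hr = fc.HeartRateSeries(t=t, hr=70 + 2 * np.sin(2 * np.pi * 0.3 * t), rate=10.0)
        out = fc.compute_hrv_series(hr, window_s=30.0, step_s=5.0)
        assert np.all(out.hrv > 0.9)

    def test_rsa_in_first_half_only(self):
        t = np.arange(0, 240, 0.1)
        mod = np.where(t < 120, np.sin(2 * np.pi * 0.3 * t), 0.0)
        lf = 0.5 * np.sin(2 * np.pi * 0.08 * t)
        hr = fc.HeartRateSeries(t=t, hr=70 + 2 * mod + lf, rate=10.0)
        out = fc.compute_hrv_series(hr, window_s=30.0, step_s=5.0)
        first = out.hrv[out.t < 120]
        second = out.hrv[out.t >= 120]
        assert np.nanmean(first) > np.nanmean(second)

    def test_window_longer_than_record_rejected(self):
        hr = fc.HeartRateSeries(t=np.arange(0, 20, 0.1), hr=np.full(200, 70.0), rate=10.0)
        with pytest.raises(ValueError):
            fc.compute_hrv_series(hr, window_s=30.0)


class TestRecovery:
    def test_episode_mean_hr_recovered(self, fnirs_session):
        hr, _ = fc.hr_hrv_from_optical(fnirs_session.optical)
        truth = fnirs_session.truth.true_hr
        errs = []
        for ep in fnirs_session.layout.episodes:
            sel = ep.contains(hr.t)
            errs.append(hr.hr[sel].mean() - truth[sel].mean())
        assert np.sqrt(np.mean(np.square(errs))) < 2.0

    def test_hr_hrv_anticorrelated_within_session(self):
        # arousal raises HR and suppresses RSA, so within a session the
        # episode means of HR and HRV move in opposite directions; centring
        # per subject removes the between-subject base-HR variation, which
        # scales RSA amplitude and would otherwise mask the coupling
        hr_means, hrv_means = [], []
        for i in range(6):
            cfg = SimulationConfig(
                n_subjects=1, seed=400 + i,
                layout=simulate.default_layout(task_s=120, rest_s=60, baseline_s=60),
            )
            s = simulate.simulate_cohort(cfg, signals=("fnirs",))[0]
            hr, hrv = fc.hr_hrv_from_optical(s.optical)
            hrs = [hr.hr[ep.contains(hr.t)].mean() for ep in s.layout.episodes]
            hrvs = [np.nanmean(hrv.hrv[ep.contains(hrv.t)]) for ep in s.layout.episodes]
            hr_means.extend(np.asarray(hrs) - np.mean(hrs))
            hrv_means.extend(np.asarray(hrvs) - np.mean(hrvs))
        assert np.corrcoef(hr_means, hrv_means)[0, 1] < 0
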