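"""Generator properties: determinism, ground-truth structure, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from cogload import simulate
from cogload.simulate import (
    ConfigurationError,
    Episode,
    LoadEffects,
    SessionLayout,
    SimulationConfig,
    default_layout,
    simulate_blink_times,
    simulate_hr_truth,
    synthesize_eeg,
    synthesize_fnirs,
)


class TestLayout:
    def test_default_layout_has_seven_episodes(self):
        layout = default_layout()
        assert len(layout.episodes) == 7
        assert [e.label for e in layout.episodes] == [
            "Baseline", "Rest", "Task1", "Rest", "Task2", "Rest", "Task1R",
        ]

    @pytest.mark.parametrize(
        "episodes",
        [
            (Episode("Rest", 0, 60),),                      # no task
            (Episode("Task1", 0, 60),),                     # no rest
            (Episode("Rest", 0, 60), Episode("Task1", 30, 90)),   # overlap
            (Episode("Rest", 0, 60), Episode("Task1", 60, 1000)),  # > 900 s task
        ],
    )
    def test_invalid_layouts_rejected(self, episodes):
        with pytest.raises(ConfigurationError):
            SessionLayout(tuple(episodes))

    def test_resp_freq_outside_hf_band_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(resp_freq=0.05)


class TestHRTruth:
    def test_constant_when_rsa_and_drift_off(self, rng):
        hr = simulate_hr_truth(70.0, 0.0, 0.25, 30.0, rng)
        assert np.allclose(hr, 70.0)

    def test_rsa_amplitude_arithmetic(self, rng):
        hr = simulate_hr_truth(70.0, 0.05, 0.25, 60.0, rng)
        assert hr.max() == pytest.approx(73.5, abs=0.01)
        assert hr.min() == pytest.approx(66.5, abs=0.01)

    def test_spectral_peak_at_resp_freq(self, rng):
        hr = simulate_hr_truth(70.0, 0.05, 0.25, 120.0, rng, rate=10.0)
        f, pxx = signal.periodogram(hr - hr.mean(), fs=10.0)
        assert f[np.argmax(pxx)] == pytest.approx(0.25, abs=0.02)

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_hr_truth(20.0, 0.0, 0.25, 10.0, rng)
        with pytest.raises(ValueError):
            simulate_hr_truth(70.0, -0.1, 0.25, 10.0, rng)


class TestBlinkTimes:
    def test_zero_rate_gives_no_blinks(self, rng):
        assert simulate_blink_times(0.0, 300.0, rng).size == 0

    def test_refractory_period_respected(self, rng):
        times = simulate_blink_times(25.0, 600.0, rng, refractory_s=0.5)
        assert np.all(np.diff(times) >= 0.5)
        assert np.all(np.diff(times) > 0)

    def test_poisson_mean_count(self):
        # rate 14/min over 300 s: expected 70, Poisson sd sqrt(70)
        counts = [
            simulate_blink_times(14.0, 300.0, np.random.default_rng(i)).size
            for i in range(200)
        ]
        mean = np.mean(counts)
        assert abs(mean - 70.0) < 3 * np.sqrt(70.0 / 200)


class TestFnirsSynthesis:
    def test_output_shape(self, fnirs_session, short_config):
        rec = fnirs_session.optical
        n_expected = int(short_config.layout.duration * short_config.fnirs_rate)
        assert rec.samples.shape == (2 * short_config.n_fnirs_channels, n_expected)
        assert set(rec.wavelengths) == set(short_config.wavelengths)

    def test_noiseless_recovery_of_beat_periods(self, rng):
        from cogload import fnirs_cardiac

        cfg = SimulationConfig(noise_sd=0.0, mayer_amplitude=0.0, drift_sd=0.0)
        hr_true = simulate_hr_truth(72.0, 0.0, 0.3, 120.0, rng)
        rec = synthesize_fnirs(hr_true, cfg, rng)
        hemo = fnirs_cardiac.convert_beer_lambert(rec)
        cardiac = fnirs_cardiac.extract_cardiac_waveform(hemo)
        beats = fnirs_cardiac.detect_beat_periods(cardiac, cfg.fnirs_rate)
        inner = beats.periods[2:-2]
        assert np.allclose(inner, 60.0 / 72.0, atol=1.0 / cfg.fnirs_rate)

    def test_noise_degrades_recovery_monotonically(self):
        from cogload import fnirs_cardiac

        rmses = []
        for noise in (0.1, 0.8, 3.0):
            errs = []
            for rep in range(3):
                rng = np.random.default_rng(100 + rep)
                cfg = SimulationConfig(noise_sd=noise)
                hr_true = simulate_hr_truth(70.0, 0.05, 0.3, 120.0, rng)
                rec = synthesize_fnirs(hr_true, cfg, rng)
                hr, _ = fnirs_cardiac.hr_hrv_from_optical(rec)
                errs.append(np.sqrt(np.mean((hr.hr - hr_true) ** 2)))
            rmses.append(np.mean(errs))
        assert rmses[0] < rmses[1] < rmses[2]

    def test_cardiac_spectral_peak_in_band(self, fnirs_session):
        from cogload import fnirs_cardiac

        hemo = fnirs_cardiac.convert_beer_lambert(fnirs_session.optical)
        cardiac = fnirs_cardiac.extract_cardiac_waveform(hemo)
        f, pxx = signal.periodogram(cardiac, fs=10.0)
        peak = f[np.argmax(pxx)]
        assert 0.5 <= peak <= 2.0


class TestEEGSynthesis:
    def test_zero_blinks_means_no_frontal_excess(self, rng):
        cfg = SimulationConfig()
        eeg = synthesize_eeg(np.empty(0), cfg, rng, duration=30.0)
        assert eeg.samples.shape[0] == cfg.n_eeg_channels
        var = eeg.samples.var(axis=1)
        assert var.max() / var.min() < 3.0   # no rank-one frontal inflation

    def test_frontal_variance_exceeds_posterior_with_blinks(self, rng):
        cfg = SimulationConfig()
        blinks = simulate_blink_times(20.0, 60.0, rng)
        eeg = synthesize_eeg(blinks, cfg, rng, duration=60.0)
        names = np.asarray(eeg.channel_names)
        var = eeg.samples.var(axis=1)
        frontal = var[np.isin(names, ["Fp1", "Fp2"])].mean()
        posterior = var[np.isin(names, ["O1", "O2", "Pz"])].mean()
        assert frontal > 2 * posterior


class TestBehaviour:
    def test_nasa_scores_are_multiples_of_five(self, rng):
        cfg = SimulationConfig()
        loads = {lab: {"arousal": a, "engagement": a}
                 for lab, a in [("Baseline", 0.5), ("Rest", 0.0), ("Task1", 1.2),
                                ("Task2", 0.9), ("Task1R", 0.6)]}
        _, targets, _ = simulate.simulate_behaviour(loads, cfg.layout, cfg, rng)
        cols = [c for c in targets.columns if c.startswith("nasa_") and c != "nasa_tlx_avg"]
        vals = targets[cols].to_numpy()
        assert np.all(vals % 5 == 0)
        assert np.all((vals >= 0) & (vals <= 100))

    def test_beep_intervals_within_range(self, rng):
        cfg = SimulationConfig()
        loads = {lab: {"arousal": 0.5, "engagement": 0.5}
                 for lab in ("Baseline", "Rest", "Task1", "Task2", "Task1R")}
        log, _, _ = simulate.simulate_behaviour(loads, cfg.layout, cfg, rng)
        gaps = np.diff(log.stimulus_onsets)
        within_episode = gaps[gaps <= cfg.beep_interval_range[1] + 1e-9]
        assert within_episode.min() >= cfg.beep_interval_range[0] - 1e-9
        assert (np.asarray(log.stimulus_durations) >= 500).all()
        assert (np.asarray(log.stimulus_durations) <= 1000).all()


class TestCohort:
    def test_cohort_size_and_episode_count(self):
        cfg = SimulationConfig(
            n_subjects=4, seed=3,
            layout=default_layout(task_s=60, rest_s=30, baseline_s=30),
        )
        bundles = simulate.simulate_cohort(cfg, signals=())
        assert len(bundles) == 4
        for b in bundles:
            assert len(b.layout.episodes) == 7
            assert len(b.targets) == 3   # one row per task episode

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=5, eeg_rate=400.0,
            layout=default_layout(task_s=30, rest_s=20, baseline_s=20),
        )
        a = simulate.simulate_cohort(cfg)[0]
        b = simulate.simulate_cohort(cfg)[0]
        assert np.array_equal(a.optical.samples, b.optical.samples)
        assert np.array_equal(a.eeg.samples, b.eeg.samples)
        assert np.array_equal(a.truth.true_blink_times, b.truth.true_blink_times)
        pd.testing.assert_frame_equal(a.targets, b.targets)

    def test_monotone_couplings_across_subjects(self):
        cfg = SimulationConfig(n_subjects=31, seed=21)
        arousal, engagement, hr, rsa, br = [], [], [], [], []
        for s in simulate.iter_cohort(cfg, signals=()):
            for ep in s.layout.task_episodes:
                arousal.append(s.truth.true_load[ep.label]["arousal"])
                engagement.append(s.truth.true_load[ep.label]["engagement"])
                sel = ep.contains(np.arange(s.truth.true_hr.size) / cfg.fnirs_rate)
                hr.append(s.truth.true_hr[sel].mean())
                rsa.append(s.truth.true_rsa_depth[ep.label])
                br.append(s.truth.true_blink_rate[ep.label])
        assert np.corrcoef(arousal, hr)[0, 1] > 0
        assert np.corrcoef(arousal, rsa)[0, 1] < 0
        assert np.corrcoef(engagement, br)[0, 1] < 0

    def test_null_effects_leave_hr_flat_across_episodes(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=0, hr_drift_sd=0.0,
            load_effects=LoadEffects(hr_bpm=0.0, rsa_depth=0.0, blink_per_min=0.0),
            layout=default_layout(task_s=60, rest_s=30, baseline_s=30),
        )
        diffs = []
        for i in range(40):
            c = SimulationConfig(**{**cfg.__dict__, "seed": i})
            s = simulate.simulate_cohort(c, signals=())[0]
            t = np.arange(s.truth.true_hr.size) / c.fnirs_rate
            task = np.mean([s.truth.true_hr[ep.contains(t)].mean() for ep in c.layout.task_episodes])
            rest = np.mean([
                s.truth.true_hr[ep.contains(t)].mean()
                for ep in c.layout.episodes if ep.label == "Rest"
            ])
            diffs.append(task - rest)
        # with all effects off, episode means differ only through the shared
        # RSA phase; the task-rest difference must straddle zero
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05
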