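import numpy as np
import pytest
from scipy import signal as sps

import eegfatigue as ef
from eegfatigue.simulate import (
    DEFAULT_ERROR_PHASES,
    DEFAULT_FATIGUE_PHASES,
    TRIAL_TIME_CAP,
    Phase,
    SimConfig,
    simulate_session_trials,
    step_trajectory,
)


def band_power_fraction(x, sfreq, lo, hi):
    """FFT oracle: fraction of total periodogram power inside [lo, hi]."""
    freqs, psd = sps.periodogram(x, fs=sfreq)
    sel = (freqs >= lo) & (freqs <= hi)
    return psd[sel].sum() / psd.sum()


class TestSimulateEEG:
    def test_seed_determinism(self):
        cfg = SimConfig(duration=4.0, seed=99)
        a, _ = ef.simulate_eeg(cfg)
        b, _ = ef.simulate_eeg(cfg)
        assert np.array_equal(a.data, b.data)

    def test_pure_alpha_spectral_fidelity(self):
        cfg = SimConfig(
            duration=10.0, band_amplitudes={"alpha": 10.0}, noise_rms=0.0, seed=3
        )
        rec, labels = ef.simulate_eeg(cfg)
        assert band_power_fraction(rec.data[0], rec.sfreq, 8, 11) >= 0.90
        assert set(labels) == {"alert"}
        assert np.std(rec.data[0]) == pytest.approx(10.0, rel=0.05)

    @pytest.mark.parametrize("band,lo,hi", [("theta", 4, 7), ("delta", 1, 4)])
    def test_pure_band_spectral_fidelity(self, band, lo, hi):
        cfg = SimConfig(
            duration=10.0, band_amplitudes={band: 5.0}, noise_rms=0.0, seed=4
        )
        rec, _ = ef.simulate_eeg(cfg)
        assert band_power_fraction(rec.data[0], rec.sfreq, lo, hi) >= 0.90

    def test_drift_reduces_alpha_power_second_half(self):
        cfg = SimConfig(
            duration=20.0, band_amplitudes={"alpha": 10.0}, noise_rms=0.0, seed=3
        )
        traj = step_trajectory(cfg.n_epochs, cfg.n_epochs // 2)
        rec, labels = ef.simulate_eeg(cfg, traj)
        half = rec.n_samples // 2
        p_first = np.mean(rec.data[0, :half] ** 2)
        p_second = np.mean(rec.data[0, half:] ** 2)
        assert p_second < p_first
        assert list(labels[: cfg.n_epochs // 2]) == ["alert"] * (cfg.n_epochs // 2)
        assert list(labels[cfg.n_epochs // 2 :]) == ["fatigued"] * (cfg.n_epochs // 2)

    def test_direction_switch_increases_power(self):
        cfg = SimConfig(
            duration=20.0,
            band_amplitudes={"alpha": 10.0},
            noise_rms=0.0,
            direction=+1,
            seed=3,
        )
        traj = step_trajectory(cfg.n_epochs, cfg.n_epochs // 2)
        rec, _ = ef.simulate_eeg(cfg, traj)
        half = rec.n_samples // 2
        assert np.mean(rec.data[0, half:] ** 2) > np.mean(rec.data[0, :half] ** 2)

    @pytest.mark.parametrize("kwargs", [{"duration": -1.0}, {"sampling_rate": 0.0}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_trajectory_length_checked(self):
        cfg = SimConfig(duration=10.0)
        with pytest.raises(ValueError, match="epochs"):
            ef.simulate_eeg(cfg, np.zeros(3))


class TestInjectArtifacts:
    def test_zero_count_is_identity(self, short_alert_record):
        out, events = ef.inject_artifacts(short_alert_record, "blink", 0)
        assert np.array_equal(out.data, short_alert_record.data)
        assert events == []

    def test_three_blinks_three_disjoint_intervals(self, short_alert_record):
        out, events = ef.inject_artifacts(short_alert_record, "blink", 3, seed=5)
        assert len(events) == 3
        over = np.abs(out.data[0]) > 50.0
        starts = sorted(e.start for e in events)
        stops = sorted(e.stop for e in events)
        assert all(a < b for a, b in zip(stops, starts[1:]))  # disjoint windows
        # every event window contains supra-threshold samples ...
        for e in events:
            assert over[e.start : e.stop].any()
        # ... and no supra-threshold sample lies outside the 3 windows
        outside = over.copy()
        for e in events:
            outside[e.start : e.stop] = False
        assert not outside.any()
        assert not (np.abs(short_alert_record.data[0]) > 50).any()

    def test_spikes_exceed_cutoff(self, short_alert_record):
        out, events = ef.inject_artifacts(short_alert_record, "spike", 2, seed=1)
        for e in events:
            assert np.abs(out.data[0, e.start : e.stop]).max() > 50.0

    def test_line_noise_dominant_peak_at_mains(self, short_alert_record):
        out, _ = ef.inject_artifacts(
            short_alert_record, "line", 1, seed=2, mains_freq=50.0
        )
        freqs, psd = sps.periodogram(out.data[0], fs=out.sfreq)
        assert freqs[np.argmax(psd)] == pytest.approx(50.0, abs=0.2)

    def test_unknown_kind_rejected(self, short_alert_record):
        with pytest.raises(ValueError, match="kind"):
            ef.inject_artifacts(short_alert_record, "cough", 1)


class TestSimulateTrials:
    def test_phase3_error_model_noise_free(self):
        series = ef.simulate_trials([Phase(13, 20, -5.96, 0.62)], noise_sd=0.0)
        at_20 = series.loc[series["trial"] == 20, "value"].item()
        assert at_20 == pytest.approx(-5.96 + 0.62 * 20)  # 6.44
        assert at_20 == pytest.approx(6.44)

    def test_zero_slope_constant_series(self):
        series = ef.simulate_trials([Phase(1, 10, 2.0, 0.0)], noise_sd=0.0)
        assert np.array_equal(series["value"].to_numpy(), np.full(10, 2.0))

    def test_completion_time_never_exceeds_cap(self):
        series = ef.simulate_trials(
            [Phase(1, 50, 290.0, 1.0)], noise_sd=30.0, cap=TRIAL_TIME_CAP, seed=8
        )
        assert (series["value"] <= 300.0).all()
        assert (series["value"] >= 0.0).all()

    def test_overlapping_phases_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ef.simulate_trials([Phase(1, 10, 0, 0), Phase(5, 20, 0, 0)])

    def test_gap_between_phases_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ef.simulate_trials([Phase(1, 5, 0, 0), Phase(8, 10, 0, 0)])

    def test_seed_determinism(self):
        a = ef.simulate_trials(DEFAULT_ERROR_PHASES, noise_sd=1.0, seed=4)
        b = ef.simulate_trials(DEFAULT_ERROR_PHASES, noise_sd=1.0, seed=4)
        assert a.equals(b)

    def test_default_phase_models_are_contiguous(self):
        for phases in (DEFAULT_ERROR_PHASES, DEFAULT_FATIGUE_PHASES):
            series = ef.simulate_trials(phases, noise_sd=0.0, cap=None)
            assert list(series["trial"]) == list(range(1, 21))

    def test_session_table_has_all_metrics(self):
        table = simulate_session_trials(noise_sd=0.5, seed=11)
        assert list(table.columns) == [
            "trial",
            "errors",
            "completion_time",
            "fatigue_value",
        ]
        assert (table["completion_time"] <= 300.0).all()
        assert (table["errors"] >= 0).all()
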