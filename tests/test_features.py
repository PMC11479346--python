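import numpy as np
import pytest

from vimsdetect.features import (FEATURE_COLUMNS, SaccadeEvent, breath_events,
                                 detect_r_peaks, detect_saccades, eda_decompose,
                                 eda_features, eeg_band_features, efrp_features,
                                 extract_features, hr_features, resp_features,
                                 saccade_features)
from vimsdetect.recordings import ChannelSignal, PipelineConfig, ValidationError

FS = 250.0


def _ecg_from_beats(beat_times, duration, fs=FS, amp=800.0):
    """Impulse train convolved with a narrow Gaussian R wave."""
    n = int(duration * fs)
    x = np.zeros(n)
    t = np.arange(-0.04, 0.04, 1 / fs)
    tmpl = amp * np.exp(-t ** 2 / (2 * 0.008 ** 2))
    c = int(np.argmax(tmpl))
    for b in beat_times:
        i0 = int(round(b * fs)) - c
        j0, j1 = max(i0, 0), min(i0 + tmpl.size, n)
        if j1 > j0:
            x[j0:j1] += tmpl[j0 - i0:j1 - i0]
    return ChannelSignal("ecg", fs, 0.0, x)


class TestDetectRPeaks:
    def test_constant_60_bpm(self):
        beats = np.arange(0.5, 60.0, 1.0)
        peaks = detect_r_peaks(_ecg_from_beats(beats, 60.0))
        rr = np.diff(peaks)
        assert np.all(np.abs(rr - 1.0) <= 1.0 / FS + 1e-9)

    def test_flatline_raises(self):
        flat = ChannelSignal("ecg", FS, 0.0, np.zeros(int(30 * FS)))
        with pytest.raises(ValidationError, match="no rhythm"):
            detect_r_peaks(flat)

    def test_90_bpm_count(self):
        beats = np.arange(0.3, 30.0, 60.0 / 90.0)
        peaks = detect_r_peaks(_ecg_from_beats(beats, 30.0))
        assert 44 <= peaks.size <= 46

    def test_strictly_increasing(self):
        beats = np.arange(0.5, 40.0, 0.8)
        peaks = detect_r_peaks(_ecg_from_beats(beats, 40.0))
        assert np.all(np.diff(peaks) > 0)


class TestHrFeatures:
    def test_constant_rr(self):
        peaks = np.arange(0.0, 70.0, 1.0)
        out = hr_features(peaks, (30.0, 60.0))
        assert out["HR_mean"] == pytest.approx(60.0, abs=1e-6)
        assert out["HR_sd"] == pytest.approx(0.0, abs=1e-6)
        assert out["LF"] == pytest.approx(0.0, abs=1e-9)
        assert out["HF"] == pytest.approx(0.0, abs=1e-9)

    @staticmethod
    def _modulated_peaks(f_mod, depth=0.05, duration=70.0):
        beats = [0.0]
        while beats[-1] < duration:
            t = beats[-1]
            beats.append(t + 1.0 * (1 + depth * np.sin(2 * np.pi * f_mod * t)))
        return np.asarray(beats)

    def test_lf_only_modulation(self):
        out = hr_features(self._modulated_peaks(0.10), (30.0, 60.0))
        assert out["LF_HF"] > 10

    def test_hf_only_modulation(self):
        out = hr_features(self._modulated_peaks(0.30), (30.0, 60.0))
        assert out["LF_HF"] < 0.1

    def test_too_few_peaks_nan(self):
        out = hr_features(np.array([31.0, 32.0, 33.0]), (30.0, 60.0))
        assert np.isnan(out["HR_mean"])


class TestRespFeatures:
    def test_pure_1hz(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        sig = ChannelSignal("resp_accel", fs, 0.0, np.sin(2 * np.pi * 1.0 * t))
        ev = breath_events(sig)
        out = resp_features(ev, (30.0, 60.0))
        assert out["RespPeriod_mean"] == pytest.approx(1.0, abs=0.01)
        assert out["RespPeriod_sd"] == pytest.approx(0.0, abs=0.01)

    def test_alternating_periods(self):
        # event train with alternating 0.8 / 1.2 s intervals
        ev = np.cumsum([0] + [0.8, 1.2] * 40)
        out = resp_features(ev, (10.0, 70.0))
        assert out["RespPeriod_mean"] == pytest.approx(1.0, abs=0.01)
        assert out["RespPeriod_sd"] == pytest.approx(0.2, abs=0.01)

    def test_dc_signal_nan(self):
        sig = ChannelSignal("resp_accel", 50.0, 0.0, np.full(6000, 2.5))
        ev = breath_events(sig)
        out = resp_features(ev, (30.0, 60.0))
        assert np.isnan(out["RespPeriod_mean"])


class TestEdaDecompose:
    FS_EDA = 32.0

    def test_constant(self):
        n = int(600 * self.FS_EDA)
        scl, scr = eda_decompose(ChannelSignal("eda", self.FS_EDA, 0.0, np.full(n, 5.0)))
        mid = slice(n // 3, 2 * n // 3)
        assert np.allclose(scl[mid], 5.0, atol=1e-6)
        assert np.allclose(scr[mid], 0.0, atol=1e-6)

    def test_injected_pulse_integral(self):
        n = int(600 * self.FS_EDA)
        x = np.full(n, 5.0)
        tp = np.arange(0, 40, 1 / self.FS_EDA)
        pulse = np.exp(-tp / 2.5) - np.exp(-tp / 0.6)
        pulse *= 2.0 / np.trapezoid(pulse, dx=1 / self.FS_EDA)
        c = int(300 * self.FS_EDA)
        x[c:c + pulse.size] += pulse
        _, scr = eda_decompose(ChannelSignal("eda", self.FS_EDA, 0.0, x))
        a, b = int(288 * self.FS_EDA), int(318 * self.FS_EDA)
        integral = np.trapezoid(np.abs(scr[a:b + 1]), dx=1 / self.FS_EDA)
        assert integral == pytest.approx(2.0, rel=0.10)

    def test_1hz_component_is_noise(self):
        n = int(600 * self.FS_EDA)
        t = np.arange(n) / self.FS_EDA
        x = 5.0 + 0.1 * np.sin(2 * np.pi * 1.0 * t)
        _, scr = eda_decompose(ChannelSignal("eda", self.FS_EDA, 0.0, x))
        mid = slice(n // 3, 2 * n // 3)
        assert np.max(np.abs(scr[mid])) < 0.01

    def test_nan_propagated(self):
        n = int(300 * self.FS_EDA)
        x = np.full(n, 5.0)
        x[1000:1050] = np.nan
        scl, scr = eda_decompose(ChannelSignal("eda", self.FS_EDA, 0.0, x))
        assert np.isnan(scl[1000:1050]).all()
        assert np.isnan(scr[1000:1050]).all()


class TestEdaFeatures:
    def test_zero_scr(self):
        fs = 32.0
        n = int(100 * fs)
        out = eda_features(np.full(n, 5.0), np.zeros(n), fs, (30.0, 60.0))
        assert out["SCR"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_scr_integral(self):
        fs = 32.0
        n = int(100 * fs)
        out = eda_features(np.full(n, 5.0), np.full(n, 0.1), fs, (30.0, 60.0))
        assert out["SCR"] == pytest.approx(3.0, rel=0.01)

    def test_scl_ramp(self):
        fs = 32.0
        n = int(100 * fs)
        scl = np.zeros(n)
        i0, i1 = int(30 * fs), int(60 * fs)
        scl[i0:i1] = np.linspace(4.0, 6.0, i1 - i0)
        out = eda_features(scl, np.zeros(n), fs, (30.0, 60.0))
        assert out["SCL_mean"] == pytest.approx(5.0, abs=0.01)
        assert out["SCL_sd"] == pytest.approx(2.0 / np.sqrt(12), abs=0.01)

    def test_window_outside_series(self):
        with pytest.raises(ValidationError):
            eda_features(np.zeros(100), np.zeros(100), 32.0, (30.0, 60.0))


def _eog_with_steps(step_times, duration, amp=100.0, speed=3000.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros(t.size)
    tau = amp / (4 * speed)
    for st in step_times:
        x += amp / (1 + np.exp(-np.clip((t - st) / tau, -60, 60)))
    return ChannelSignal("eog_h", fs, 0.0, x)


class TestDetectSaccades:
    def test_ten_steps(self):
        steps = np.linspace(2.0, 28.0, 10)
        ev = detect_saccades(_eog_with_steps(steps, 30.0))
        assert len(ev) == 10
        out = saccade_features(ev, (0.0, 30.0))
        assert out["SaccadeFreq"] == pytest.approx(10 / 30, abs=1e-9)

    def test_constant_eog(self):
        sig = ChannelSignal("eog_h", FS, 0.0, np.full(int(30 * FS), 42.0))
        assert detect_saccades(sig) == []

    def test_peak_speed_recovered(self):
        ev = detect_saccades(_eog_with_steps([5.0], 10.0, amp=120.0, speed=3000.0))
        assert len(ev) == 1
        assert ev[0].peak_speed == pytest.approx(3000.0, rel=0.05)

    def test_event_ordering_fields(self):
        with pytest.raises(ValidationError):
            SaccadeEvent(onset_s=1.0, offset_s=0.5, peak_speed=100.0)
        with pytest.raises(ValidationError):
            SaccadeEvent(onset_s=1.0, offset_s=1.1, peak_speed=-5.0)


class TestSaccadeFeatures:
    def _events(self, speeds, t0=1.0, gap=1.0):
        return [SaccadeEvent(t0 + i * gap, t0 + i * gap + 0.04, s)
                for i, s in enumerate(speeds)]

    def test_fifteen_identical(self):
        out = saccade_features(self._events([2000.0] * 15), (0.0, 30.0))
        assert out == {"SaccadeFreq": pytest.approx(0.5),
                       "SaccadeSpeed_mean": pytest.approx(2000.0),
                       "SaccadeSpeed_sd": pytest.approx(0.0)}

    def test_no_events(self):
        out = saccade_features([], (0.0, 30.0))
        assert out["SaccadeFreq"] == 0.0
        assert np.isnan(out["SaccadeSpeed_mean"])
        assert np.isnan(out["SaccadeSpeed_sd"])

    def test_sample_sd(self):
        out = saccade_features(self._events([1000.0, 2000.0, 3000.0]), (0.0, 30.0))
        assert out["SaccadeSpeed_mean"] == pytest.approx(2000.0)
        assert out["SaccadeSpeed_sd"] == pytest.approx(1000.0)


class TestEegBandFeatures:
    def _signal(self, values, fs=FS):
        return ChannelSignal("eeg_avg", fs, 0.0, values)

    def test_pure_alpha(self):
        t = np.arange(int(40 * FS)) / FS
        sig = self._signal(10.0 * np.sin(2 * np.pi * 10.0 * t))
        out = eeg_band_features(sig, (0.0, 30.0))
        assert out["AlphaRatio_mean"] == pytest.approx(1.0, abs=0.01)
        assert out["PeakAlphaFreq_mean"] == pytest.approx(10.0, abs=1e-9)
        assert out["ThetaRatio_mean"] == pytest.approx(0.0, abs=0.01)

    def test_pure_theta(self):
        t = np.arange(int(40 * FS)) / FS
        sig = self._signal(5.0 * np.sin(2 * np.pi * 6.0 * t))
        out = eeg_band_features(sig, (0.0, 30.0))
        assert out["ThetaRatio_mean"] == pytest.approx(1.0, abs=0.01)
        assert out["PeakThetaFreq_mean"] == pytest.approx(6.0, abs=1e-9)

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(5)
        sig = self._signal(rng.standard_normal(int(40 * FS)))
        out = eeg_band_features(sig, (0.0, 30.0))
        expected = (13 - 8) / (30 - 0.5)
        assert out["AlphaRatio_mean"] == pytest.approx(expected, abs=0.03)

    def test_too_few_valid_subwindows(self):
        vals = np.full(int(40 * FS), np.nan)
        vals[: int(10 * FS)] = 1.0
        out = eeg_band_features(self._signal(vals), (0.0, 30.0))
        assert np.isnan(out["AlphaRatio_mean"])


class TestEfrpFeatures:
    @staticmethod
    def _eeg_with_lambda(fixations, duration, amp=8.0, latency_ms=100.0,
                         noise=0.0, rng=None, fs=FS):
        n = int(duration * fs)
        x = np.zeros(n)
        t = np.arange(-0.1, 0.1, 1 / fs)
        tmpl = amp * np.exp(-t ** 2 / (2 * 0.02 ** 2))
        c = int(np.argmax(tmpl))
        for f in fixations:
            i0 = int(round((f + latency_ms / 1000.0) * fs)) - c
            j0, j1 = max(i0, 0), min(i0 + tmpl.size, n)
            x[j0:j1] += tmpl[j0 - i0:j1 - i0]
        if noise:
            x += noise * rng.standard_normal(n)
        return ChannelSignal("eeg_avg", fs, 0.0, x)

    @staticmethod
    def _saccades_at(fixations):
        return [SaccadeEvent(f - 0.05, f, 2000.0) for f in fixations]

    def test_injected_template(self):
        fix = np.arange(2.0, 28.0, 1.7)
        sig = self._eeg_with_lambda(fix, 30.0)
        out = efrp_features(sig, self._saccades_at(fix), (0.0, 30.0))
        assert out["LambdaAmplitude"] == pytest.approx(8.0, rel=0.02)
        assert out["LambdaLatency"] == pytest.approx(100.0, abs=1000.0 / FS + 1e-6)

    def test_flat_eeg(self):
        fix = np.arange(2.0, 28.0, 2.0)
        sig = ChannelSignal("eeg_avg", FS, 0.0, np.zeros(int(30 * FS)))
        out = efrp_features(sig, self._saccades_at(fix), (0.0, 30.0))
        assert out["LambdaAmplitude"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_fixations(self):
        fix = [5.0, 10.0]
        sig = self._eeg_with_lambda(np.asarray(fix), 30.0)
        out = efrp_features(sig, self._saccades_at(fix), (0.0, 30.0))
        assert np.isnan(out["LambdaAmplitude"])

    def test_averaging_shrinks_error(self):
        # amplitude error with 20 epochs beats 5 epochs in >=90% of trials
        wins = 0
        trials = 200
        for k in range(trials):
            rng = np.random.default_rng(k)
            fix20 = np.arange(2.0, 2.0 + 20 * 1.4, 1.4)
            fix5 = fix20[:5]
            sig = self._eeg_with_lambda(fix20, 35.0, noise=15.0, rng=rng)
            out20 = efrp_features(sig, self._saccades_at(fix20), (0.0, 35.0))
            out5 = efrp_features(sig, self._saccades_at(fix5), (0.0, 35.0))
            if abs(out20["LambdaAmplitude"] - 8.0) < abs(out5["LambdaAmplitude"] - 8.0):
                wins += 1
        assert wins >= 0.9 * trials


class TestExtractFeatures:
    def test_row_and_column_count(self, features_default):
        tbl = features_default.table
        assert len(tbl) == 360 - 30
        assert tuple(tbl.columns) == FEATURE_COLUMNS
        assert len(FEATURE_COLUMNS) == 23

    def test_determinism(self, default_session):
        rec, _ = default_session
        t1 = extract_features(rec).table
        t2 = extract_features(rec).table
        assert t1.equals(t2)

    def test_short_session_rejected(self, default_session):
        import dataclasses
        rec, _ = default_session
        short = dataclasses.replace(rec, duration_s=150.0, reports=[])
        short.duration_s = 149.0  # bypass Recording's own validation
        with pytest.raises(ValidationError):
            extract_features(short)

    def test_window_locality(self, default_session):
        """Perturbing the signal well after t leaves row t's event-window
        statistics essentially unchanged (filters have finite memory)."""
        import copy
        rec, _ = default_session
        rec2 = copy.deepcopy(rec)
        for name in ("eog_h", "ecg"):
            ch = rec2.channels[name]
            i0 = int((rec.duration_s - 30) * ch.sample_rate)
            ch.values[i0:] += 500.0 * np.sin(np.arange(ch.values.size - i0))
        t_probe = int(rec.duration_s) - 120
        row1 = extract_features(rec).table.loc[t_probe]
        row2 = extract_features(rec2).table.loc[t_probe]
        for col in ("SaccadeFreq", "SaccadeSpeed_mean", "HR_mean"):
            assert row1[col] == pytest.approx(row2[col], rel=1e-6, abs=1e-9)
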