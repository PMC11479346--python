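"""Window-based extraction of the 23 physiological features at 1-s resolution.

Every feature at timestamp ``t`` (integer seconds) summarises the half-open
trailing window ``[t - 30, t)``; the first valid timestamp is 30.  All
filters are zero-phase 4th-order Butterworth so event timing stays unbiased.
NaN is a first-class citizen: windows with too little usable signal yield
NaN features which are repaired downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, periodogram, sosfiltfilt

from .recordings import (EEG_CHANNELS, ChannelSignal, PipelineConfig,
                         Recording, ValidationError)

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureSeries",
    "SaccadeEvent",
    "bandpass",
    "detect_r_peaks",
    "hr_features",
    "resp_features",
    "eda_decompose",
    "eda_features",
    "detect_saccades",
    "saccade_features",
    "eeg_band_features",
    "efrp_features",
    "extract_features",
]

#: the 23 feature columns, in canonical (importance-table) order
FEATURE_COLUMNS = (
    "HR_mean", "HR_sd", "LF", "HF", "LF_HF",
    "RespPeriod_mean", "RespPeriod_sd",
    "SCL_mean", "SCL_sd", "SCR",
    "SaccadeFreq", "SaccadeSpeed_mean", "SaccadeSpeed_sd",
    "ThetaRatio_mean", "AlphaRatio_mean", "ThetaRatio_sd", "AlphaRatio_sd",
    "PeakThetaFreq_mean", "PeakAlphaFreq_mean", "PeakThetaFreq_sd", "PeakAlphaFreq_sd",
    "LambdaAmplitude", "LambdaLatency",
)


@dataclass(frozen=True)
class SaccadeEvent:
    onset_s: float
    offset_s: float
    peak_speed: float  # uV/s, peak |d(EOG)/dt| within the event

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValidationError("saccade onset must precede offset")
        if self.peak_speed <= 0:
            raise ValidationError("saccade peak_speed must be positive")


@dataclass
class FeatureSeries:
    """1-Hz table of the 23 features for one session."""

    participant_id: str
    display_condition: str
    timestamps: np.ndarray  # integer seconds, 30 .. duration-1
    table: pd.DataFrame     # index = timestamps, columns = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        if tuple(self.table.columns) != FEATURE_COLUMNS:
            raise ValidationError("feature table columns must equal the canonical 23-name list")


# -- filtering helpers ------------------------------------------------------


def _filtfilt_nan(sos, x: np.ndarray) -> np.ndarray:
    """Zero-phase filter that tolerates NaN spans: gaps are bridged by linear
    interpolation for filtering, then re-imposed on the output."""
    nan = ~np.isfinite(x)
    if nan.all():
        return np.full_like(x, np.nan)
    if nan.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    y = sosfiltfilt(sos, x)
    if nan.any():
        y[nan] = np.nan
    return y


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return _filtfilt_nan(sos, x)


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    sos = butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _filtfilt_nan(sos, x)


def highpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return _filtfilt_nan(sos, x)


def _sample_sd(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")


# -- ECG --------------------------------------------------------------------


def detect_r_peaks(ecg: ChannelSignal, cfg: PipelineConfig | None = None) -> np.ndarray:
    """R-peak times (s) from a raw ECG channel.

    Band-pass filter, then an enhancement chain (derivative, squaring, 150-ms
    moving integration) with an adaptive threshold at 50% of the running
    median of the last eight accepted enhanced peaks.  Peaks closer than the
    0.3-s physiological floor are merged (the larger survives).
    """
    cfg = cfg or PipelineConfig()
    fs = ecg.sample_rate
    x = bandpass(ecg.values, fs, cfg.ecg_bandpass)
    x = np.nan_to_num(x)
    deriv = np.gradient(x) * fs
    enhanced = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    kernel = np.ones(win) / win
    enhanced = np.convolve(enhanced, kernel, mode="same")

    from scipy.signal import find_peaks
    floor = 0.05 * np.percentile(enhanced, 99) if enhanced.size else 0.0
    cand, _ = find_peaks(enhanced, distance=max(int(0.3 * fs), 1), height=floor)
    if cand.size == 0:
        raise ValidationError("no rhythm: no detectable R peaks")

    accepted: list[int] = []
    recent: list[float] = []
    for i in cand:
        h = enhanced[i]
        thr = 0.5 * float(np.median(recent[-8:])) if recent else floor
        if h >= thr:
            accepted.append(i)
            recent.append(h)
    if len(accepted) < 2:
        raise ValidationError("no rhythm: fewer than 2 R peaks")

    # refine each peak to the local ECG maximum within +/-50 ms
    half = int(round(0.05 * fs))
    refined = []
    for i in accepted:
        j0, j1 = max(i - half, 0), min(i + half + 1, x.size)
        refined.append(j0 + int(np.argmax(x[j0:j1])))
    refined = np.unique(refined)

    # enforce the 0.3-s lower RR gate: merge too-close detections
    times = ecg.start_time + refined / fs
    keep = [0]
    for k in range(1, times.size):
        if times[k] - times[keep[-1]] < 0.3:
            if x[refined[k]] > x[refined[keep[-1]]]:
                keep[-1] = k
        else:
            keep.append(k)
    times = times[keep]
    if times.size < 2:
        raise ValidationError("no rhythm: fewer than 2 R peaks")
    return times


def instantaneous_hr_series(r_peaks: np.ndarray,
                            rr_gate: tuple[float, float] = (0.3, 2.0),
                            ) -> tuple[np.ndarray, np.ndarray]:
    """(times, bpm): instantaneous HR = 60/RR placed at the second beat of
    each in-gate RR interval; out-of-gate intervals are dropped."""
    rr = np.diff(r_peaks)
    ok = (rr >= rr_gate[0]) & (rr <= rr_gate[1])
    return r_peaks[1:][ok], 60.0 / rr[ok]


def hr_features(r_peaks: np.ndarray, window: tuple[float, float],
                cfg: PipelineConfig | None = None) -> dict[str, float]:
    """HR_mean/HR_sd/LF/HF/LF_HF over one 30-s window.

    The beat-wise instantaneous HR is cubic-spline interpolated and resampled
    at 50 Hz on the window; LF/HF are integrated Hann-periodogram power in
    0.04-0.15 and 0.15-0.40 Hz.
    """
    cfg = cfg or PipelineConfig()
    t0, t1 = window
    nan = {k: float("nan") for k in ("HR_mean", "HR_sd", "LF", "HF", "LF_HF")}
    bt, bpm = instantaneous_hr_series(np.asarray(r_peaks, dtype=float))
    # spline support: beats in the window plus one on each side for stability
    inside = np.flatnonzero((bt >= t0) & (bt < t1))
    if inside.size < 4:
        return nan
    lo = max(int(inside[0]) - 1, 0)
    hi = min(int(inside[-1]) + 2, bt.size)
    bt_s, bpm_s = bt[lo:hi], bpm[lo:hi]
    if np.any(np.diff(bt_s) <= 0):
        keep = np.concatenate([[True], np.diff(bt_s) > 0])
        bt_s, bpm_s = bt_s[keep], bpm_s[keep]
    if bt_s.size < 4:
        return nan
    spline = CubicSpline(bt_s, bpm_s, bc_type="natural", extrapolate=True)
    fs = cfg.hr_resample_hz
    grid = t0 + np.arange(int(round((t1 - t0) * fs))) / fs
    hr = spline(grid)
    out = {"HR_mean": float(np.mean(hr)), "HR_sd": _sample_sd(hr)}
    freqs, psd = periodogram(hr - np.mean(hr), fs=fs, window="hann")
    df = freqs[1] - freqs[0]
    lf = float(np.sum(psd[(freqs >= cfg.lf_band[0]) & (freqs <= cfg.lf_band[1])]) * df)
    hf = float(np.sum(psd[(freqs >= cfg.hf_band[0]) & (freqs <= cfg.hf_band[1])]) * df)
    with np.errstate(divide="ignore", invalid="ignore"):
        out.update(LF=lf, HF=hf, LF_HF=float(np.divide(lf, hf)))
    return out


# -- respiration ------------------------------------------------------------


def breath_events(resp: ChannelSignal, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Breath event times: positive-going zero crossings of the differenced,
    band-passed accelerometer signal."""
    cfg = cfg or PipelineConfig()
    x = bandpass(resp.values, resp.sample_rate, cfg.resp_bandpass)
    finite = x[np.isfinite(x)]
    if finite.size == 0 or float(np.sqrt(np.mean(finite ** 2))) < 1e-9:
        return np.array([])  # no oscillation survives the band-pass
    d = np.diff(x)
    d = np.nan_to_num(d)
    sign = d > 0
    crossings = np.flatnonzero(~sign[:-1] & sign[1:]) + 1
    # sub-sample refinement by linear interpolation of the differenced signal
    times = []
    for i in crossings:
        d0, d1 = d[i - 1], d[i]
        frac = -d0 / (d1 - d0) if d1 != d0 else 0.0
        times.append(resp.start_time + (i - 1 + frac) / resp.sample_rate)
    return np.asarray(times)


def resp_features(events: np.ndarray, window: tuple[float, float]) -> dict[str, float]:
    """Mean/sd of the respiration period over intervals whose onset lies in
    the window."""
    t0, t1 = window
    ev = np.asarray(events, dtype=float)
    periods = np.diff(ev)
    onsets = ev[:-1]
    sel = periods[(onsets >= t0) & (onsets < t1)]
    if sel.size < 1:
        return {"RespPeriod_mean": float("nan"), "RespPeriod_sd": float("nan")}
    return {"RespPeriod_mean": float(np.mean(sel)), "RespPeriod_sd": _sample_sd(sel)}


# -- EDA --------------------------------------------------------------------


def eda_decompose(eda: ChannelSignal, cfg: PipelineConfig | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split skin conductance into (SCL, SCR) series of the input's length.

    SCL is the <0.04 Hz tonic component; the >0.5 Hz content is treated as
    noise; SCR is the de-noised signal minus SCL.
    """
    cfg = cfg or PipelineConfig()
    x = eda.values
    fs = eda.sample_rate
    scl = lowpass(x, fs, cfg.scl_lowpass_hz)
    noise = highpass(x, fs, cfg.eda_noise_highpass_hz)
    scr = (x - noise) - scl
    return scl, scr


def eda_features(scl: np.ndarray, scr: np.ndarray, fs: float,
                 window: tuple[float, float], start_time: float = 0.0) -> dict[str, float]:
    """SCL mean/sd over window samples; SCR = integral of |SCR| (uS*s)."""
    t0, t1 = window
    i0 = int(round((t0 - start_time) * fs))
    i1 = int(round((t1 - start_time) * fs))
    if i0 < 0 or i1 > len(scl):
        raise ValidationError("window outside the decomposed EDA series")
    seg_scl = scl[i0:i1]
    # include the right endpoint so the integral spans the full window length
    seg_scr = scr[i0:min(i1 + 1, len(scr))]
    finite = np.isfinite(seg_scr)
    integral = (float(np.trapezoid(np.abs(seg_scr[finite]), dx=1.0 / fs))
                if finite.sum() >= 2 else float("nan"))
    return {
        "SCL_mean": float(np.nanmean(seg_scl)) if np.isfinite(seg_scl).any() else float("nan"),
        "SCL_sd": _sample_sd(seg_scl),
        "SCR": integral,
    }


# -- EOG / saccades ---------------------------------------------------------


def detect_saccades(eog: ChannelSignal, cfg: PipelineConfig | None = None) -> list[SaccadeEvent]:
    """Saccades from horizontal EOG: spans where |velocity| exceeds an
    adaptive threshold (6 x trailing-30-s MAD of the velocity, floored at
    an absolute minimum speed), lasting 10-150 ms; spans separated by less
    than 50 ms are merged."""
    cfg = cfg or PipelineConfig()
    fs = eog.sample_rate
    x = np.nan_to_num(eog.values)
    # forward difference: narrowest usable derivative kernel, so the peak of
    # fast (<10 ms) transitions is attenuated least
    vel = np.empty_like(x)
    vel[:-1] = np.diff(x) * fs
    vel[-1] = vel[-2] if x.size > 1 else 0.0
    n = vel.size

    # detection runs on a 20-ms-smoothed velocity (noise suppression); the
    # reported peak speed comes from the raw derivative so fast transients
    # are not attenuated
    k = max(int(round(0.020 * fs)), 1)
    vel_det = np.convolve(vel, np.ones(k) / k, mode="same")
    abs_det = np.abs(vel_det)
    abs_vel = np.abs(vel)

    # threshold series at 1-s resolution from the trailing 30-s MAD
    step = max(int(round(fs)), 1)
    span = int(round(30 * fs))
    thr = np.full(n, cfg.saccade_speed_floor)
    for s in range(0, n, step):
        j0 = max(s - span, 0)
        seg = abs_det[j0:max(s, step)]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        thr[s:s + step] = max(cfg.saccade_mad_factor * 1.4826 * mad,
                              cfg.saccade_speed_floor)

    above = abs_det > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    span_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    span_ends = np.concatenate([idx[breaks], [idx[-1]]])

    merge_gap = cfg.saccade_merge_gap_ms / 1000.0 * fs
    merged: list[list[int]] = []
    for s0, s1 in zip(span_starts, span_ends):
        if merged and s0 - merged[-1][1] < merge_gap:
            merged[-1][1] = s1
        else:
            merged.append([int(s0), int(s1)])

    events = []
    lo = cfg.saccade_min_duration_ms / 1000.0
    hi = cfg.saccade_max_duration_ms / 1000.0
    for s0, s1 in merged:
        # the smoothing kernel smears span edges outward by ~k/2 samples;
        # tighten them on the raw velocity so event timing stays unbiased
        inner = np.flatnonzero(abs_vel[s0:s1 + 1] > thr[s0:s1 + 1])
        if inner.size:
            s0, s1 = s0 + int(inner[0]), s0 + int(inner[-1])
        dur = (s1 - s0 + 1) / fs
        if not lo <= dur <= hi:
            continue
        peak = float(np.max(abs_vel[s0:s1 + 1]))
        events.append(SaccadeEvent(onset_s=eog.start_time + s0 / fs,
                                   offset_s=eog.start_time + (s1 + 1) / fs,
                                   peak_speed=peak))
    return events


def saccade_features(events: list[SaccadeEvent], window: tuple[float, float],
                     ) -> dict[str, float]:
    t0, t1 = window
    speeds = np.array([e.peak_speed for e in events if t0 <= e.onset_s < t1])
    freq = speeds.size / (t1 - t0)
    if speeds.size == 0:
        return {"SaccadeFreq": 0.0, "SaccadeSpeed_mean": float("nan"),
                "SaccadeSpeed_sd": float("nan")}
    return {"SaccadeFreq": float(freq),
            "SaccadeSpeed_mean": float(np.mean(speeds)),
            "SaccadeSpeed_sd": _sample_sd(speeds)}


# -- EEG --------------------------------------------------------------------


def average_eeg(rec: Recording, cfg: PipelineConfig | None = None) -> ChannelSignal:
    """Band-pass (0.5-30 Hz) each of the four EEG channels, then average."""
    cfg = cfg or PipelineConfig()
    chans = [rec.channels[name] for name in EEG_CHANNELS]
    fs = chans[0].sample_rate
    n = min(c.values.size for c in chans)
    stack = np.vstack([bandpass(c.values[:n], fs, cfg.eeg_bandpass) for c in chans])
    return ChannelSignal("eeg_avg", fs, chans[0].start_time, stack.mean(axis=0))


def _subwindow_spectrum(x: np.ndarray, fs: float):
    return periodogram(x, fs=fs)


def eeg_band_features(avg_eeg: ChannelSignal, window: tuple[float, float],
                      cfg: PipelineConfig | None = None,
                      _cache: dict | None = None) -> dict[str, float]:
    """Theta/alpha power ratios and peak frequencies over 15 non-overlapping
    2-s subwindows of the 30-s window: mean and sd of each across subwindows.

    The ratio denominator is the total power in the analysed 0.5-30 Hz band.
    """
    cfg = cfg or PipelineConfig()
    fs = avg_eeg.sample_rate
    t0, t1 = window
    sub = cfg.eeg_subwindow_s
    n_sub = int((t1 - t0) // sub)
    nsamp = int(round(sub * fs))
    theta_r, alpha_r, theta_f, alpha_f = [], [], [], []
    for k in range(n_sub):
        start = t0 + k * sub
        i0 = int(round((start - avg_eeg.start_time) * fs))
        if i0 < 0 or i0 + nsamp > avg_eeg.values.size:
            continue
        if _cache is not None and i0 in _cache:
            freqs, psd = _cache[i0]
        else:
            seg = avg_eeg.values[i0:i0 + nsamp]
            if not np.isfinite(seg).all():
                if np.isfinite(seg).any():
                    continue  # partially usable subwindows are skipped
                continue
            freqs, psd = _subwindow_spectrum(seg, fs)
            if _cache is not None:
                _cache[i0] = (freqs, psd)
        total_mask = (freqs >= cfg.eeg_bandpass[0]) & (freqs <= cfg.eeg_bandpass[1])
        th_mask = (freqs >= cfg.theta_band[0]) & (freqs <= cfg.theta_band[1])
        al_mask = (freqs >= cfg.alpha_band[0]) & (freqs <= cfg.alpha_band[1])
        total = float(np.sum(psd[total_mask]))
        if total <= 0:
            continue
        theta_r.append(float(np.sum(psd[th_mask])) / total)
        alpha_r.append(float(np.sum(psd[al_mask])) / total)
        theta_f.append(float(freqs[th_mask][np.argmax(psd[th_mask])]))
        alpha_f.append(float(freqs[al_mask][np.argmax(psd[al_mask])]))
    names = ("ThetaRatio_mean", "AlphaRatio_mean", "ThetaRatio_sd", "AlphaRatio_sd",
             "PeakThetaFreq_mean", "PeakAlphaFreq_mean", "PeakThetaFreq_sd", "PeakAlphaFreq_sd")
    if len(theta_r) < 8:
        return {k: float("nan") for k in names}
    return {
        "ThetaRatio_mean": float(np.mean(theta_r)),
        "AlphaRatio_mean": float(np.mean(alpha_r)),
        "ThetaRatio_sd": _sample_sd(np.asarray(theta_r)),
        "AlphaRatio_sd": _sample_sd(np.asarray(alpha_r)),
        "PeakThetaFreq_mean": float(np.mean(theta_f)),
        "PeakAlphaFreq_mean": float(np.mean(alpha_f)),
        "PeakThetaFreq_sd": _sample_sd(np.asarray(theta_f)),
        "PeakAlphaFreq_sd": _sample_sd(np.asarray(alpha_f)),
    }


def efrp_features(avg_eeg: ChannelSignal, saccades: list[SaccadeEvent],
                  window: tuple[float, float],
                  cfg: PipelineConfig | None = None) -> dict[str, float]:
    """Lambda-response amplitude/latency of the eye-fixation-related potential.

    Epochs of -100..+300 ms around each fixation onset (= saccade offset) in
    the window are baseline-corrected by their -100..0 ms mean and averaged;
    the amplitude is the maximum of the average in 50-200 ms post-fixation
    and the latency is the time of that maximum.
    """
    cfg = cfg or PipelineConfig()
    fs = avg_eeg.sample_rate
    t0, t1 = window
    onsets = [e.offset_s for e in saccades if t0 <= e.offset_s < t1]
    nan = {"LambdaAmplitude": float("nan"), "LambdaLatency": float("nan")}
    if len(onsets) < 3:
        return nan
    pre = int(round(-cfg.efrp_epoch_ms[0] / 1000.0 * fs))
    post = int(round(cfg.efrp_epoch_ms[1] / 1000.0 * fs))
    epochs = []
    for onset in onsets:
        c = int(round((onset - avg_eeg.start_time) * fs))
        if c - pre < 0 or c + post > avg_eeg.values.size:
            continue
        seg = avg_eeg.values[c - pre:c + post]
        if not np.isfinite(seg).all():
            continue
        epochs.append(seg - np.mean(seg[:pre]))
    if len(epochs) < 3:
        return nan
    avg = np.mean(epochs, axis=0)
    rel_ms = (np.arange(avg.size) - pre) / fs * 1000.0
    mask = (rel_ms >= cfg.lambda_window_ms[0]) & (rel_ms <= cfg.lambda_window_ms[1])
    seg = avg[mask]
    k = int(np.argmax(seg))
    return {"LambdaAmplitude": float(seg[k]), "LambdaLatency": float(rel_ms[mask][k])}


# -- full extraction --------------------------------------------------------


def extract_features(rec: Recording, cfg: PipelineConfig | None = None) -> FeatureSeries:
    """Compute the full 23-column, 1-Hz feature table for one session."""
    cfg = cfg or PipelineConfig()
    if rec.duration_s < 150:
        raise ValidationError("session shorter than 150 s: no baseline + labelled data")

    try:
        r_peaks = detect_r_peaks(rec.channels["ecg"], cfg)
    except ValidationError:
        r_peaks = np.array([])
    breaths = breath_events(rec.channels["resp_accel"], cfg)
    scl, scr = eda_decompose(rec.channels["eda"], cfg)
    eda_fs = rec.channels["eda"].sample_rate
    eda_t0 = rec.channels["eda"].start_time
    saccades = detect_saccades(rec.channels["eog_h"], cfg)
    eeg = average_eeg(rec, cfg)

    timestamps = np.arange(cfg.window_s, int(rec.duration_s), cfg.step_s)
    rows = []
    spectrum_cache: dict = {}
    for t in timestamps:
        window = (float(t - cfg.window_s), float(t))
        row: dict[str, float] = {}
        if r_peaks.size >= 2:
            row.update(hr_features(r_peaks, window, cfg))
        else:
            row.update({k: float("nan") for k in ("HR_mean", "HR_sd", "LF", "HF", "LF_HF")})
        row.update(resp_features(breaths, window))
        row.update(eda_features(scl, scr, eda_fs, window, eda_t0))
        row.update(saccade_features(saccades, window))
        row.update(eeg_band_features(eeg, window, cfg, _cache=spectrum_cache))
        row.update(efrp_features(eeg, saccades, window, cfg))
        rows.append(row)

    table = pd.DataFrame(rows, index=pd.Index(timestamps, name="t_s"))[list(FEATURE_COLUMNS)]
    return FeatureSeries(participant_id=rec.participant_id,
                         display_condition=rec.display_condition,
                         timestamps=timestamps, table=table)
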