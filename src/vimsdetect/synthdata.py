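"""Synthetic multichannel physiological sessions with a known VIMS trajectory.

Each session is driven by a latent severity curve ``g(t)`` in [0, 1] that is
mapped to reported levels 1-5 by fixed thresholds.  Every channel is coupled
to ``g`` with a configurable signed effect size so that downstream feature
extractors can be validated against injected ground truth:

* ECG: R-peak train at ``HR0 * (1 + d_hr * g)`` bpm with sinusoidal RR
  modulation in the LF (0.1 Hz) and HF (0.3 Hz) bands, convolved with a
  biphasic Gaussian-derivative QRS template.
* Respiration accelerometer: oscillation with period ``P0 * (1 + d_p * g)``.
* EDA: rising tonic level plus bi-exponential phasic pulses (rise 1 s,
  decay 4 s, unit-area scaled) at a rate rising with ``g``, plus >0.5 Hz noise.
* Horizontal EOG: step saccades (logistic transitions of known peak slope)
  at a rate falling with ``g`` and a peak speed rising with ``g``.
* EEG x4: 1/f background, a 10 Hz oscillator whose power falls with ``g``,
  a 6 Hz oscillator whose power rises with ``g``, and a lambda-response
  template after every fixation onset whose amplitude and latency rise
  with ``g``.

A report is emitted at every task-cycle boundary; a level-5 report
terminates the session at that instant, so generated label series never
contain 5 and severity trajectories are non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .recordings import ChannelSignal, Recording, ReportEvent, ValidationError

__all__ = ["ScenarioConfig", "GroundTruth", "simulate_session", "simulate_cohort"]

#: latent-severity thresholds for levels 2, 3, 4 and 5
LEVEL_THRESHOLDS = (0.25, 0.45, 0.65, 0.95)


def _levels(g: np.ndarray) -> np.ndarray:
    """Map latent severity in [0, 1] to an integer VIMS level 1-5."""
    return 1 + np.searchsorted(LEVEL_THRESHOLDS, np.asarray(g, dtype=float), side="right")


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of one simulated session; the seed fully determines the output."""

    duration_s: float = 600.0
    report_interval_s: float = 60.0
    severity: str = "severe"  # mild | severe
    onset_frac: float = 0.0   # fraction of the session before severity starts rising
    seed: int = 0

    # sample rates (Hz) -- deployment defaults, configurable
    fs_ecg: float = 250.0
    fs_resp: float = 50.0
    fs_eda: float = 32.0
    fs_eog: float = 250.0
    fs_eeg: float = 250.0

    # channel baselines
    hr0_bpm: float = 70.0
    resp_period0_s: float = 0.9
    scl0_us: float = 5.0
    scr_rate0_hz: float = 0.08
    scr_area_us_s: float = 0.5
    saccade_rate0_hz: float = 1.2
    saccade_speed0_uvps: float = 2500.0
    saccade_amp_uv: tuple[float, float] = (60.0, 140.0)
    alpha_amp0_uv: float = 10.0
    theta_amp0_uv: float = 5.0
    lambda_amp0_uv: float = 8.0
    lambda_latency0_ms: float = 100.0
    qrs_amp_uv: float = 800.0

    # fractional change from baseline at full severity (g = 1); signs fixed
    effect_sizes: dict = field(default_factory=lambda: {
        "hr": 0.15,
        "resp_period": 0.30,
        "scl": 0.60,
        "scr_rate": 2.0,
        "saccade_freq": -0.55,
        "saccade_speed": 0.40,
        "alpha": -0.55,
        "theta": 0.90,
        "lambda_amp": 0.60,
        "lambda_latency": 0.35,
    })

    # RR-interval sinusoidal modulation depths (LF at 0.1 Hz, HF at 0.3 Hz)
    rr_mod_lf: float = 0.02
    rr_mod_hf: float = 0.03

    # emit only the phasic electrodermal component (constant tonic level and
    # no sub-0.04 Hz pulse mass), so SCR is the sole EDA information channel
    eda_phasic_only: bool = False

    # additive noise amplitudes per channel (0 => deterministic channel)
    noise: dict = field(default_factory=lambda: {
        "ecg": 8.0,        # uV white + slow wander
        "resp_accel": 0.02,  # m/s^2
        "eda": 0.008,      # uS, high-pass filtered >0.5 Hz
        "scl_drift": 0.15,   # uS random-walk tonic wander (sub-0.04 Hz)
        "eog_h": 4.0,      # uV
        "eeg": 3.0,        # uV 1/f + white
    })

    def noise_free(self) -> "ScenarioConfig":
        """Copy with all stochastic/nuisance components silenced (effects kept)."""
        return replace(self, noise={k: 0.0 for k in self.noise},
                       rr_mod_lf=0.0, rr_mod_hf=0.0)

    def _check(self) -> None:
        if self.severity not in ("mild", "severe"):
            raise ValidationError(f"severity must be mild or severe, got {self.severity!r}")
        if self.duration_s < max(150.0, self.report_interval_s + 120.0):
            raise ValidationError(
                f"duration_s {self.duration_s} too short for a baseline plus one report")
        signs = {"hr": 1, "resp_period": 1, "scl": 1, "scr_rate": 1,
                 "saccade_freq": -1, "saccade_speed": 1, "alpha": -1,
                 "theta": 1, "lambda_amp": 1, "lambda_latency": 1}
        for key, sign in signs.items():
            v = self.effect_sizes.get(key, 0.0)
            if v * sign < 0:
                raise ValidationError(f"effect size {key}={v} has the wrong sign")


@dataclass
class GroundTruth:
    """Injected session dynamics, tabulated at 1 Hz plus discrete event lists."""

    times: np.ndarray               # 1-Hz grid, 0 .. duration-1
    g: np.ndarray                   # latent severity in [0, 1]
    vims_level: np.ndarray          # integer level 1-4 on the grid (5 never appears)
    instantaneous_hr: np.ndarray    # bpm
    resp_period: np.ndarray         # s
    scl: np.ndarray                 # uS (tonic component)
    alpha_power_fraction: np.ndarray
    theta_power_fraction: np.ndarray
    lambda_amplitude: np.ndarray    # uV
    lambda_latency: np.ndarray      # ms
    scr_events: list                # [(time_s, area uS*s), ...]
    saccades: list                  # [(onset_s, peak_speed uV/s), ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.vims_level) < 0):
            raise ValidationError("VIMS trajectory must be non-decreasing")


def _g_curve(t: np.ndarray, cfg: ScenarioConfig, duration: float) -> np.ndarray:
    g_max = 1.0 if cfg.severity == "severe" else 0.35
    t_on = cfg.onset_frac * duration
    span = max(duration - t_on, 1e-9)
    return g_max * np.clip((np.asarray(t, dtype=float) - t_on) / span, 0.0, 1.0)


def _qrs_template(fs: float, amp: float) -> np.ndarray:
    # biphasic Gaussian-derivative wave, ~80 ms wide; positive lobe = R peak
    sigma = 0.010
    t = np.arange(-0.04, 0.04 + 1e-12, 1.0 / fs)
    w = -(t / sigma) * np.exp(-t * t / (2 * sigma * sigma))
    return amp * w / np.max(np.abs(w))


def _add_pulses(trace: np.ndarray, fs: float, centers: Iterable[float],
                template: np.ndarray, center_index: int) -> None:
    n = trace.size
    for c in centers:
        i0 = int(round(c * fs)) - center_index
        j0, j1 = max(i0, 0), min(i0 + template.size, n)
        if j1 > j0:
            trace[j0:j1] += template[j0 - i0:j1 - i0]


def _one_over_f_noise(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    if amp == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    pink *= amp / max(np.std(pink), 1e-12)
    return pink + 0.3 * amp * rng.standard_normal(n)


def simulate_session(cfg: ScenarioConfig,
                     participant_id: str = "P01",
                     display_condition: str = "MD") -> tuple[Recording, GroundTruth]:
    """Generate one seeded session; returns the Recording and its ground truth."""
    cfg._check()
    rng = np.random.default_rng(cfg.seed)
    eff = cfg.effect_sizes

    # -- reports & termination ---------------------------------------------
    report_times = np.arange(cfg.report_interval_s, cfg.duration_s + 1e-9,
                             cfg.report_interval_s)
    levels_at_reports = _levels(_g_curve(report_times, cfg, cfg.duration_s))
    duration = float(cfg.duration_s)
    if np.any(levels_at_reports >= 5):
        stop = int(np.argmax(levels_at_reports >= 5))
        report_times = report_times[: stop + 1]
        levels_at_reports = levels_at_reports[: stop + 1]
        levels_at_reports[-1] = 5
        duration = float(report_times[-1])
    reports = [
        ReportEvent(time_s=float(t), vims_level=int(lv),
                    drowsiness=int(rng.integers(1, 3)), fatigue=int(rng.integers(1, 3)))
        for t, lv in zip(report_times, levels_at_reports)
    ]

    def g_of(t):
        return _g_curve(np.asarray(t, dtype=float), cfg, float(cfg.duration_s))

    # -- ECG ----------------------------------------------------------------
    beat_times = []
    t = 0.5  # first beat clear of the array edge so the QRS is not clipped
    while t < duration + 1.0:
        beat_times.append(t)
        hr = cfg.hr0_bpm * (1.0 + eff.get("hr", 0.0) * float(g_of(t)))
        rr = (60.0 / hr) * (1.0
                            + cfg.rr_mod_lf * np.sin(2 * np.pi * 0.1 * t)
                            + cfg.rr_mod_hf * np.sin(2 * np.pi * 0.3 * t))
        t += rr
    beat_times = np.asarray(beat_times)

    n_ecg = int(round(duration * cfg.fs_ecg))
    ecg = np.zeros(n_ecg)
    tmpl = _qrs_template(cfg.fs_ecg, cfg.qrs_amp_uv)
    # positive lobe of the Gaussian derivative sits one sigma before centre;
    # shift the template so the R maximum lands on the beat time
    peak_idx = int(np.argmax(tmpl))
    _add_pulses(ecg, cfg.fs_ecg, beat_times[beat_times < duration + 0.05], tmpl, peak_idx)
    t_ecg = np.arange(n_ecg) / cfg.fs_ecg
    ecg += cfg.noise["ecg"] * rng.standard_normal(n_ecg)
    ecg += 10.0 * cfg.noise["ecg"] * np.sin(2 * np.pi * 0.02 * t_ecg)  # baseline wander

    # -- respiration --------------------------------------------------------
    n_resp = int(round(duration * cfg.fs_resp))
    t_resp = np.arange(n_resp) / cfg.fs_resp
    period = cfg.resp_period0_s * (1.0 + eff.get("resp_period", 0.0) * g_of(t_resp))
    phase = np.cumsum(1.0 / (period * cfg.fs_resp))
    resp = np.sin(2 * np.pi * phase) + cfg.noise["resp_accel"] * rng.standard_normal(n_resp)

    # -- EDA ----------------------------------------------------------------
    n_eda = int(round(duration * cfg.fs_eda))
    t_eda = np.arange(n_eda) / cfg.fs_eda
    scl_truth = cfg.scl0_us * (1.0 + eff.get("scl", 0.0) * g_of(t_eda))
    eda = scl_truth.copy()
    drift_amp = cfg.noise.get("scl_drift", 0.0)
    if drift_amp > 0:
        walk = np.cumsum(rng.standard_normal(n_eda))
        eda += drift_amp * walk / max(np.std(walk), 1e-12)
    scr_events: list[tuple[float, float]] = []
    t = 5.0
    while t < duration - 10.0:
        rate = cfg.scr_rate0_hz * (1.0 + eff.get("scr_rate", 0.0) * float(g_of(t)))
        gap = float(rng.exponential(1.0 / max(rate, 1e-6)))
        t += max(gap, 2.0)
        if t >= duration - 10.0:
            break
        scr_events.append((t, cfg.scr_area_us_s))
    # kinetics chosen so the downstream tonic/phasic decomposition recovers
    # a window-integral close to the injected pulse area (slower pulses lose
    # too much mass to the 0.04 Hz tonic estimate)
    tau_r, tau_d = 0.6, 2.5
    t_pulse = np.arange(0.0, 25.0, 1.0 / cfg.fs_eda)
    pulse = np.exp(-t_pulse / tau_d) - np.exp(-t_pulse / tau_r)
    pulse *= cfg.scr_area_us_s / np.trapezoid(pulse, dx=1.0 / cfg.fs_eda)
    if cfg.eda_phasic_only:
        from scipy.signal import butter, sosfiltfilt
        phasic = np.zeros(n_eda)
        _add_pulses(phasic, cfg.fs_eda, [e[0] for e in scr_events], pulse, 0)
        sos = butter(4, 0.04, btype="lowpass", fs=cfg.fs_eda, output="sos")
        eda = np.full(n_eda, cfg.scl0_us) + phasic - sosfiltfilt(sos, phasic)
    else:
        _add_pulses(eda, cfg.fs_eda, [e[0] for e in scr_events], pulse, 0)
    if cfg.noise["eda"] > 0:
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, 0.5, btype="highpass", fs=cfg.fs_eda, output="sos")
        eda = eda + sosfiltfilt(sos, cfg.noise["eda"] * rng.standard_normal(n_eda))

    # -- EOG ----------------------------------------------------------------
    n_eog = int(round(duration * cfg.fs_eog))
    t_eog = np.arange(n_eog) / cfg.fs_eog
    eog = np.zeros(n_eog)
    step_offsets = np.zeros(n_eog)  # saturated-step tails, applied via cumsum
    saccades: list[tuple[float, float]] = []
    fixation_onsets: list[float] = []
    pos = 0.0
    t = 1.0
    while t < duration - 1.0:
        rate = cfg.saccade_rate0_hz * (1.0 + eff.get("saccade_freq", 0.0) * float(g_of(t)))
        gap = float(rng.exponential(1.0 / max(rate, 1e-6)))
        t += max(gap, 0.30)
        if t >= duration - 1.0:
            break
        amp = float(rng.uniform(*cfg.saccade_amp_uv))
        sign = -1.0 if pos > 150.0 else (1.0 if pos < -150.0 else float(rng.choice([-1.0, 1.0])))
        amp *= sign
        speed = cfg.saccade_speed0_uvps * (1.0 + eff.get("saccade_speed", 0.0) * float(g_of(t)))
        speed *= float(rng.uniform(0.95, 1.05)) if cfg.noise["eog_h"] > 0 else 1.0
        tau = abs(amp) / (4.0 * speed)
        centre = t + 3.5 * tau
        # localized sigmoid: beyond +/-0.25 s the transition is saturated
        i0 = max(int((centre - 0.25) * cfg.fs_eog), 0)
        i1 = min(int((centre + 0.25) * cfg.fs_eog), n_eog)
        local = t_eog[i0:i1]
        eog[i0:i1] += amp / (1.0 + np.exp(-np.clip((local - centre) / tau, -60, 60)))
        if i1 < n_eog:
            step_offsets[i1] += amp
        saccades.append((t, speed))
        # the eye counts as fixated once its speed falls below the absolute
        # floor used by the saccade detector (logistic tails never reach 0)
        fixation_onsets.append(
            centre + 2.0 * tau * np.arccosh(np.sqrt(max(speed, 101.0) / 100.0)))
        pos += amp
    eog += np.cumsum(step_offsets)
    eog += cfg.noise["eog_h"] * rng.standard_normal(n_eog)

    # -- EEG ----------------------------------------------------------------
    n_eeg = int(round(duration * cfg.fs_eeg))
    t_eeg = np.arange(n_eeg) / cfg.fs_eeg
    g_eeg = g_of(t_eeg)
    alpha_amp = cfg.alpha_amp0_uv * np.sqrt(np.clip(1.0 + eff.get("alpha", 0.0) * g_eeg, 0.0, None))
    theta_amp = cfg.theta_amp0_uv * np.sqrt(np.clip(1.0 + eff.get("theta", 0.0) * g_eeg, 0.0, None))

    def _osc(f0: float) -> np.ndarray:
        # slow frequency wander (+-~0.4 Hz) so subwindow peak frequencies
        # fluctuate as in real EEG; silenced in noise-free scenarios
        if cfg.noise["eeg"] > 0:
            nodes = rng.standard_normal(max(int(duration) + 2, 2)) * 0.4
            f = f0 + np.interp(t_eeg, np.arange(nodes.size, dtype=float), nodes)
        else:
            f = np.full(n_eeg, f0)
        return np.sin(2 * np.pi * np.cumsum(f) / cfg.fs_eeg)

    base = alpha_amp * _osc(10.0) + theta_amp * _osc(6.0)
    lam_sigma = 0.025
    lam_t = np.arange(-4 * lam_sigma, 4 * lam_sigma + 1e-12, 1.0 / cfg.fs_eeg)
    lam_shape = np.exp(-lam_t ** 2 / (2 * lam_sigma ** 2))
    lam_centre_idx = int(np.argmax(lam_shape))
    lam_trace = np.zeros(n_eeg)
    for onset in fixation_onsets:
        gg = float(g_of(onset))
        amp = cfg.lambda_amp0_uv * (1.0 + eff.get("lambda_amp", 0.0) * gg)
        lat = cfg.lambda_latency0_ms * (1.0 + eff.get("lambda_latency", 0.0) * gg) / 1000.0
        _add_pulses(lam_trace, cfg.fs_eeg, [onset + lat], amp * lam_shape, lam_centre_idx)
    eeg_channels = {}
    for name in ("eeg_t5", "eeg_p3", "eeg_p4", "eeg_t6"):
        eeg_channels[name] = (base + lam_trace
                              + _one_over_f_noise(n_eeg, cfg.fs_eeg, cfg.noise["eeg"], rng))

    channels = {
        "ecg": ChannelSignal("ecg", cfg.fs_ecg, 0.0, ecg),
        "resp_accel": ChannelSignal("resp_accel", cfg.fs_resp, 0.0, resp),
        "eda": ChannelSignal("eda", cfg.fs_eda, 0.0, eda),
        "eog_h": ChannelSignal("eog_h", cfg.fs_eog, 0.0, eog),
    }
    for name, vals in eeg_channels.items():
        channels[name] = ChannelSignal(name, cfg.fs_eeg, 0.0, vals)

    rec = Recording(participant_id=participant_id, display_condition=display_condition,
                    channels=channels, reports=reports, duration_s=duration)

    grid = np.arange(int(duration))
    g_grid = g_of(grid)
    level_grid = np.minimum(_levels(g_grid), 4)
    total_power = alpha_amp ** 2 + theta_amp ** 2
    alpha_frac = np.where(total_power > 0, alpha_amp ** 2 / np.maximum(total_power, 1e-12), 0.0)
    idx = np.minimum((grid * cfg.fs_eeg).astype(int), n_eeg - 1)
    truth = GroundTruth(
        times=grid.astype(float),
        g=g_grid,
        vims_level=level_grid,
        instantaneous_hr=cfg.hr0_bpm * (1.0 + eff.get("hr", 0.0) * g_grid),
        resp_period=cfg.resp_period0_s * (1.0 + eff.get("resp_period", 0.0) * g_grid),
        scl=(np.full(grid.size, cfg.scl0_us) if cfg.eda_phasic_only
             else cfg.scl0_us * (1.0 + eff.get("scl", 0.0) * g_grid)),
        alpha_power_fraction=alpha_frac[idx],
        theta_power_fraction=1.0 - alpha_frac[idx],
        lambda_amplitude=cfg.lambda_amp0_uv * (1.0 + eff.get("lambda_amp", 0.0) * g_grid),
        lambda_latency=cfg.lambda_latency0_ms * (1.0 + eff.get("lambda_latency", 0.0) * g_grid),
        scr_events=scr_events,
        saccades=saccades,
    )
    return rec, truth


def simulate_cohort(n_participants: int,
                    template: ScenarioConfig | None = None,
                    seed: int = 0,
                    severe_fraction: float = 7.0 / 9.0,
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Simulate a cohort: two sessions (MD, HMD) per participant.

    The first ``round(severe_fraction * n)`` participants develop severe VIMS
    in at least one session (always the HMD one, sometimes both); the rest
    never exceed level 2.  Sessions of one participant share random baseline
    offsets so that participant-grouped cross-validation is meaningful.
    """
    if n_participants < 2:
        raise ValidationError("need at least 2 participants")
    template = template or ScenarioConfig()
    n_severe = int(round(severe_fraction * n_participants))
    master = np.random.SeedSequence(seed)
    out: list[tuple[Recording, GroundTruth]] = []
    for i, ss in enumerate(master.spawn(n_participants)):
        pid = f"P{i + 1:02d}"
        child_seeds = ss.generate_state(4)
        prng = np.random.default_rng(child_seeds[0])
        # participant effect: stable physiological baselines across sessions
        hr0 = template.hr0_bpm * prng.uniform(0.9, 1.1)
        scl0 = template.scl0_us * prng.uniform(0.8, 1.2)
        sacc0 = template.saccade_rate0_hz * prng.uniform(0.9, 1.1)
        period0 = template.resp_period0_s * prng.uniform(0.9, 1.1)
        severe = i < n_severe
        md_severe = severe and bool(prng.uniform() < 0.4)
        for display, sev, sseed in (("MD", md_severe, child_seeds[1]),
                                    ("HMD", severe, child_seeds[2])):
            cfg = replace(template,
                          severity="severe" if sev else "mild",
                          seed=int(sseed),
                          hr0_bpm=hr0, scl0_us=scl0,
                          saccade_rate0_hz=sacc0, resp_period0_s=period0)
            out.append(simulate_session(cfg, participant_id=pid, display_condition=display))
    return out
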