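"""Domain types, on-disk formats and configuration shared by all pipeline stages.

A recording session is stored as a directory of plain comma-separated text
files: one per physiological channel (two columns, ``time_s`` and ``value``,
preceded by a header comment carrying the channel name and sample rate), one
``events.csv`` with the timed subjective reports, and a ``metadata.json``
with session-level fields.  The format is deliberately inspectable and
round-trips losslessly (floats are serialised with shortest-repr).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CHANNEL_NAMES",
    "EEG_CHANNELS",
    "ChannelSignal",
    "ReportEvent",
    "Recording",
    "PipelineConfig",
    "ValidationError",
    "read_recording",
    "write_recording",
]

#: Required channel identifiers, in canonical order.
CHANNEL_NAMES = (
    "ecg",
    "resp_accel",
    "eda",
    "eog_h",
    "eeg_t5",
    "eeg_p3",
    "eeg_p4",
    "eeg_t6",
)

EEG_CHANNELS = ("eeg_t5", "eeg_p3", "eeg_p4", "eeg_t6")


class ValidationError(ValueError):
    """Raised when an on-disk artefact or in-memory object violates its contract."""


@dataclass
class ChannelSignal:
    """One uniformly sampled signal channel.

    ECG/EOG/EEG values are in microvolts, EDA in microsiemens and the
    respiration accelerometer in m/s^2.  Missing samples are explicit NaN.
    """

    name: str
    sample_rate: float
    start_time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValidationError(f"channel {self.name}: sample_rate must be > 0")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError(f"channel {self.name}: values must be a non-empty 1-D array")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelSignal):
            return NotImplemented
        return (
            self.name == other.name
            and self.sample_rate == other.sample_rate
            and self.start_time == other.start_time
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(frozen=True)
class ReportEvent:
    """A timed verbal report of subjective state (VIMS level 1-5)."""

    time_s: float
    vims_level: int
    drowsiness: Optional[int] = None
    fatigue: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.vims_level) <= 5:
            raise ValidationError(f"vims_level {self.vims_level} outside 1..5")
        for name in ("drowsiness", "fatigue"):
            v = getattr(self, name)
            if v is not None and not 1 <= int(v) <= 5:
                raise ValidationError(f"{name} {v} outside 1..5")


@dataclass
class Recording:
    """One participant session: all channels plus the report series."""

    participant_id: str
    display_condition: str
    channels: dict[str, ChannelSignal]
    reports: list[ReportEvent]
    duration_s: float

    def __post_init__(self) -> None:
        if self.display_condition not in ("MD", "HMD"):
            raise ValidationError(f"display_condition must be MD or HMD, got {self.display_condition!r}")
        for name in CHANNEL_NAMES:
            if name not in self.channels:
                raise ValidationError(f"channel missing: {name}")
        if self.duration_s < 150:
            raise ValidationError(f"duration_s {self.duration_s} < 150 (needs baseline + labelled data)")
        times = [r.time_s for r in self.reports]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("events unordered")
        for r in self.reports:
            if r.time_s > self.duration_s + 1e-9:
                raise ValidationError(f"event out of range: report at {r.time_s} s after duration {self.duration_s} s")
        levels = [r.vims_level for r in self.reports]
        if 5 in levels:
            if levels[-1] != 5 or levels.count(5) != 1:
                raise ValidationError("a level-5 report must be the last report")
            if not math.isclose(self.reports[-1].time_s, self.duration_s, rel_tol=0, abs_tol=1e-6):
                raise ValidationError("session must terminate at its level-5 report")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.display_condition == other.display_condition
            and self.duration_s == other.duration_s
            and self.reports == other.reports
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
        )


# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """All numeric knobs of the extraction/standardisation/model pipeline.

    Defaults are the published processing parameters; sample rates are
    deployment choices (the acquisition rates were never stated) and live in
    the simulator's scenario config instead.
    """

    window_s: int = 30
    step_s: int = 1
    baseline_span_s: int = 120
    hr_resample_hz: float = 50.0
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    ecg_bandpass: tuple[float, float] = (0.05, 30.0)
    resp_bandpass: tuple[float, float] = (0.5, 2.0)
    scl_lowpass_hz: float = 0.04
    eda_noise_highpass_hz: float = 0.5
    eeg_bandpass: tuple[float, float] = (0.5, 30.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    eeg_subwindow_s: int = 2
    lambda_window_ms: tuple[float, float] = (50.0, 200.0)
    outlier_percentiles: tuple[float, float] = (1.0, 99.0)
    trend_segments: int = 1000
    random_seed: int = 0
    # implementation details not printed anywhere: saccade detector knobs
    saccade_mad_factor: float = 6.0
    saccade_speed_floor: float = 100.0  # uV/s; lower bound on the velocity threshold
    saccade_min_duration_ms: float = 10.0
    saccade_max_duration_ms: float = 150.0
    saccade_merge_gap_ms: float = 50.0
    efrp_epoch_ms: tuple[float, float] = (-100.0, 300.0)

    def __post_init__(self) -> None:
        for name in ("lf_band", "hf_band", "ecg_bandpass", "resp_bandpass",
                     "eeg_bandpass", "alpha_band", "theta_band",
                     "lambda_window_ms", "outlier_percentiles"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: lower bound {lo} must be < upper bound {hi}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# -- serialisation ----------------------------------------------------------

_EVENT_COLUMNS = ["time_s", "vims_level", "drowsiness", "fatigue"]


def write_recording(rec: Recording, path: str | Path) -> None:
    """Serialise ``rec`` to a directory of plain-text files.

    Numeric values round-trip exactly (shortest-repr float formatting) and
    two writes of the same Recording produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in sorted(rec.channels.items()):
        fp = path / f"{name}.csv"
        with open(fp, "w") as fh:
            fh.write(f"# name={ch.name} sample_rate={ch.sample_rate!r} start_time={ch.start_time!r}\n")
            fh.write("time_s,value\n")
            times = ch.times
            fh.writelines(f"{t!r},{v!r}\n" for t, v in zip(times.tolist(), ch.values.tolist()))
    with open(path / "events.csv", "w") as fh:
        fh.write(",".join(_EVENT_COLUMNS) + "\n")
        for r in rec.reports:
            drow = "" if r.drowsiness is None else str(int(r.drowsiness))
            fat = "" if r.fatigue is None else str(int(r.fatigue))
            fh.write(f"{r.time_s!r},{int(r.vims_level)},{drow},{fat}\n")
    meta = {
        "participant_id": rec.participant_id,
        "display_condition": rec.display_condition,
        "duration_s": rec.duration_s,
    }
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_channel(fp: Path) -> ChannelSignal:
    with open(fp) as fh:
        header = fh.readline().strip()
    if not header.startswith("# "):
        raise ValidationError(f"{fp.name}: missing channel header")
    fields = dict(item.split("=", 1) for item in header[2:].split())
    name = fields["name"]
    sample_rate = float(fields["sample_rate"])
    start_time = float(fields["start_time"])
    df = pd.read_csv(fp, comment="#", float_precision="round_trip")
    values = df["value"].to_numpy(dtype=np.float64)
    times = df["time_s"].to_numpy(dtype=np.float64)
    if times.size >= 2:
        spacing = float(np.median(np.diff(times)))
        if spacing <= 0:
            raise ValidationError(f"{fp.name}: non-increasing sample times")
        inferred = 1.0 / spacing
        if abs(inferred - sample_rate) > 0.01 * sample_rate:
            raise ValidationError(
                f"{fp.name}: sample-rate mismatch (header {sample_rate} Hz, "
                f"median spacing implies {inferred:.6g} Hz)"
            )
    return ChannelSignal(name=name, sample_rate=sample_rate, start_time=start_time, values=values)


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    meta_fp = path / "metadata.json"
    if not meta_fp.exists():
        raise ValidationError(f"{path}: metadata.json not found")
    with open(meta_fp) as fh:
        meta = json.load(fh)
    channels: dict[str, ChannelSignal] = {}
    for name in CHANNEL_NAMES:
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise ValidationError(f"channel missing: {name}")
        channels[name] = _read_channel(fp)
    events = pd.read_csv(path / "events.csv")
    reports = []
    for row in events.itertuples(index=False):
        reports.append(
            ReportEvent(
                time_s=float(row.time_s),
                vims_level=int(row.vims_level),
                drowsiness=None if pd.isna(row.drowsiness) else int(row.drowsiness),
                fatigue=None if pd.isna(row.fatigue) else int(row.fatigue),
            )
        )
    return Recording(
        participant_id=str(meta["participant_id"]),
        display_condition=str(meta["display_condition"]),
        channels=channels,
        reports=reports,
        duration_s=float(meta["duration_s"]),
    )
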