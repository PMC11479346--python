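"""Label-series construction, baseline-ratio standardisation and outlier repair.

Each feature is expressed as a ratio to a per-session reference value: the
mean of the 90 feature rows with timestamps in [30, 120).  Ratios from all
sessions are pooled per feature and clipped at the empirical 1st/99th
percentiles; out-of-range or missing values are replaced by the previous
(already repaired) value in time order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, FeatureSeries
from .recordings import PipelineConfig, ReportEvent, ValidationError

__all__ = [
    "LabelSeries",
    "StandardizedFeatures",
    "build_label_series",
    "standardize",
    "fit_clip_thresholds",
    "repair_outliers",
    "assemble_dataset",
]


@dataclass
class LabelSeries:
    """Per-second VIMS level (1-4) and its binary severity class."""

    timestamps: np.ndarray
    vims_level: np.ndarray
    binary_class: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isin(self.vims_level, [1, 2, 3, 4])):
            raise ValidationError("label levels must lie in 1..4")
        if not np.array_equal(self.binary_class, (self.vims_level >= 3).astype(int)):
            raise ValidationError("binary class must be 1 exactly where level >= 3")
        if np.any(np.diff(self.vims_level) < 0):
            raise ValidationError("level series must be non-decreasing within a session")


@dataclass
class StandardizedFeatures:
    """Ratio-standardised features plus the audit trail of repairs."""

    participant_id: str
    display_condition: str
    table: pd.DataFrame                 # index t_s, columns = FEATURE_COLUMNS
    reference: pd.Series                # per-feature baseline reference value
    thresholds: pd.DataFrame | None = None   # rows: lower, upper
    repair_log: list = field(default_factory=list)  # (t_s, feature, reason)


def build_label_series(reports: list[ReportEvent], timestamps: np.ndarray) -> LabelSeries:
    """Update-and-hold labelling: the level at time t is the most recent
    report at or before t (1 before any report).  A level-5 report ends the
    series at its own timestamp, so 5 never appears."""
    timestamps = np.asarray(timestamps)
    end = None
    for r in reports:
        if r.vims_level == 5:
            end = r.time_s
            break
    if end is not None:
        timestamps = timestamps[timestamps < end]
    times = np.array([r.time_s for r in reports], dtype=float)
    levels = np.array([r.vims_level for r in reports], dtype=int)
    if times.size:
        idx = np.searchsorted(times, timestamps, side="right") - 1
        out = np.where(idx >= 0, levels[np.clip(idx, 0, None)], 1)
    else:
        out = np.ones(timestamps.size, dtype=int)
    out = np.minimum(out, 4)
    return LabelSeries(timestamps=timestamps, vims_level=out.astype(int),
                       binary_class=(out >= 3).astype(int))


def standardize(fs: FeatureSeries, cfg: PipelineConfig | None = None,
                ) -> StandardizedFeatures:
    """Divide every feature by its session baseline reference: the mean of
    the 90 rows with t in [30, baseline_span_s), NaNs excluded."""
    cfg = cfg or PipelineConfig()
    tbl = fs.table
    base = tbl.loc[(tbl.index >= cfg.window_s) & (tbl.index < cfg.baseline_span_s)]
    if len(base) == 0:
        raise ValidationError("no baseline rows: session too short")
    reference = base.mean(skipna=True)
    log = []
    for col in FEATURE_COLUMNS:
        n_ok = int(base[col].notna().sum())
        if n_ok < len(base) // 2:
            warnings.warn(f"unreliable baseline for {col}: only {n_ok} usable rows",
                          stacklevel=2)
    ratio = tbl.copy()
    for col in FEATURE_COLUMNS:
        ref = reference[col]
        if not np.isfinite(ref) or abs(ref) < 1e-9:
            ratio[col] = np.nan
            log.append((None, col, "degenerate baseline reference"))
        else:
            ratio[col] = tbl[col] / ref
    return StandardizedFeatures(participant_id=fs.participant_id,
                                display_condition=fs.display_condition,
                                table=ratio, reference=reference, repair_log=log)


def fit_clip_thresholds(sessions: list[StandardizedFeatures],
                        percentiles: tuple[float, float] = (1.0, 99.0),
                        ) -> pd.DataFrame:
    """Pool the ratio values of all sessions per feature and return the
    empirical (linear-interpolation) percentile thresholds."""
    pooled = pd.concat([s.table for s in sessions], axis=0)
    out = {}
    for col in FEATURE_COLUMNS:
        vals = pooled[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValidationError(f"feature {col} is all-NaN across the pooled sessions")
        lo, hi = np.percentile(vals, percentiles)
        out[col] = (float(lo), float(hi))
    return pd.DataFrame(out, index=["lower", "upper"])


def repair_outliers(session: StandardizedFeatures, thresholds: pd.DataFrame,
                    ) -> StandardizedFeatures:
    """Replace out-of-range or NaN values by the previous repaired value
    (a bad head is back-filled from the first in-range value)."""
    tbl = session.table.copy()
    log = list(session.repair_log)
    for col in FEATURE_COLUMNS:
        lo, hi = thresholds.loc["lower", col], thresholds.loc["upper", col]
        vals = tbl[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < lo) | (vals > hi)
        if bad.all():
            raise ValidationError(f"feature {col}: every value is out of range")
        good_idx = np.flatnonzero(~bad)
        first_good = vals[good_idx[0]]
        prev = first_good
        for i in range(vals.size):
            if bad[i]:
                reason = "missing" if not np.isfinite(vals[i]) else "out of range"
                log.append((int(tbl.index[i]), col, reason))
                vals[i] = prev
            else:
                prev = vals[i]
        tbl[col] = vals
    return StandardizedFeatures(participant_id=session.participant_id,
                                display_condition=session.display_condition,
                                table=tbl, reference=session.reference,
                                thresholds=thresholds, repair_log=log)


def assemble_dataset(sessions: list[tuple[StandardizedFeatures, LabelSeries]],
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack aligned (features, labels) pairs into one training table.

    Returns ``(dataset, counts)``: one row per second per session with
    participant/display identifiers, the 23 ratio features, the VIMS level
    and the binary class; and a per-session class-count summary.
    """
    frames = []
    count_rows = []
    for feats, labels in sessions:
        tbl = feats.table.loc[feats.table.index.isin(labels.timestamps)]
        if len(tbl) != len(labels.timestamps) or not np.array_equal(
                tbl.index.to_numpy(), labels.timestamps):
            raise ValidationError(
                f"misaligned timestamps for {feats.participant_id}/{feats.display_condition}")
        frame = tbl.reset_index()
        frame.insert(0, "participant_id", feats.participant_id)
        frame.insert(1, "display", feats.display_condition)
        frame["vims_level"] = labels.vims_level
        frame["y"] = labels.binary_class
        frames.append(frame)
        count_rows.append({
            "participant_id": feats.participant_id,
            "display": feats.display_condition,
            "n_class0": int(np.sum(labels.binary_class == 0)),
            "n_class1": int(np.sum(labels.binary_class == 1)),
        })
    dataset = pd.concat(frames, ignore_index=True)
    counts = pd.DataFrame(count_rows)
    return dataset, counts
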