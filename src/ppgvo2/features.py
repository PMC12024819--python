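"""Signal chain: raw multiwavelength PPG to per-window absorbance-slope features.

The quasi-DC pipeline is deliberately simple.  Photodiodes are combined into
two groups (PD1 horizontal, PD2 vertical); the 100 Hz photocurrents are
reduced to 0.1 Hz by non-overlapping 10-s block means, which suppresses the
cardiac (AC) ripple and much of the motion noise; each window's Beer-Lambert
absorbance A(l) = -ln(I(l) / I0*(l)) is computed against the white-card
calibration at the 50 mA operating point; and an ordinary-least-squares fit
of A against wavelength (nm) yields one slope per photodiode group per
window — the features m1 and m2.  Together with the subject's height and
weight these four numbers are what the ensemble model sees.

Window convention: windows start at t=0 of the record, are non-overlapping,
10 s long and half-open [start, end); a trailing partial window is dropped.
Reference VO2 (breath-by-breath, irregular) is aligned by averaging all
reference samples whose timestamps fall inside a window; windows with no
overlapping reference sample are dropped and counted.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, reference_intensity
from .spectra import DEVICE_WAVELENGTHS_NM, fit_wavelength_slope

__all__ = [
    "PPGRecord",
    "VO2Trace",
    "channel_name",
    "parse_channel",
    "combine_pd_groups",
    "downsample_dc",
    "absorbance",
    "window_slopes",
    "build_feature_table",
    "read_ppg_csv",
    "write_ppg_csv",
    "read_vo2_csv",
    "write_vo2_csv",
    "read_subjects_json",
    "write_subjects_json",
    "FEATURE_FILE_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 10.0

FEATURE_FILE_COLUMNS = (
    "subject_id",
    "t_center_s",
    "m1",
    "m2",
    "height_cm",
    "weight_kg",
    "vo2_ref",
)

_CHANNEL_RE = re.compile(r"^w(?P<wl>\d+)_(?P<tag>[a-z0-9]+)$")


def channel_name(wavelength_nm: int, tag: str) -> str:
    """Column name for a channel, e.g. ``w670_pd1``."""
    return f"w{int(wavelength_nm)}_{tag}"


def parse_channel(name: str) -> tuple[int, str]:
    """Split ``w670_pd1`` into ``(670, 'pd1')``; the tag may also be a raw diode id."""
    m = _CHANNEL_RE.match(name)
    if m is None:
        raise ValueError(f"not a channel column name: {name!r} (expected w<nm>_<tag>)")
    return int(m.group("wl")), m.group("tag")


@dataclass
class PPGRecord:
    """Uniformly sampled multichannel photocurrent record.

    ``signal`` holds one column per channel, named ``w<wavelength>_<tag>``
    where the tag is a photodiode group (``pd1``/``pd2``) or, before
    combination, a raw diode identifier.  Values are photocurrents in uA.
    """

    t: np.ndarray
    signal: pd.DataFrame
    sampling_rate_hz: float
    subject_id: str = ""
    drive_ma: float = 50.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size != len(self.signal):
            raise ValueError("t and signal must have the same number of samples")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("timestamps must be uniformly spaced (to 1e-9 s)")
        for col in self.signal.columns:
            parse_channel(col)  # validates naming

    @property
    def n_samples(self) -> int:
        return self.t.size

    def channels(self) -> list[tuple[int, str]]:
        return [parse_channel(c) for c in self.signal.columns]

    def pd_groups(self) -> list[str]:
        return sorted({tag for _, tag in self.channels()})

    def wavelengths(self) -> list[int]:
        return sorted({wl for wl, _ in self.channels()})


@dataclass
class VO2Trace:
    """Reference oxygen-uptake time series (mL/kg/min), e.g. breath-by-breath."""

    t: np.ndarray
    vo2: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.t.shape != self.vo2.shape or self.t.ndim != 1:
            raise ValueError("t and vo2 must be 1-D arrays of equal length")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be ascending")
        if np.any(self.vo2 <= 0):
            raise ValueError("VO2 values must be strictly positive")


def combine_pd_groups(
    raw: PPGRecord, groups: Mapping[str, Sequence[str]] | None = None
) -> PPGRecord:
    """Average raw photodiode channels into PD-group channels.

    ``groups`` maps each output group tag to the raw diode tags it contains,
    e.g. ``{"pd1": ["a", "b"], "pd2": ["c", "d"]}`` for the horizontal and
    vertical diode pairs.  With no mapping, channels already tagged
    ``pd1``/``pd2`` pass through unchanged.
    """
    if groups is None:
        groups = {"pd1": ["pd1"], "pd2": ["pd2"]}
    out: dict[str, np.ndarray] = {}
    wavelengths = raw.wavelengths()
    for group, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"photodiode group {group!r} has no member diodes")
        for wl in wavelengths:
            cols = [channel_name(wl, m) for m in members]
            missing = [c for c in cols if c not in raw.signal.columns]
            if missing:
                raise ValueError(f"group {group!r}: missing diode channels {missing}")
            out[channel_name(wl, group)] = raw.signal[cols].to_numpy().mean(axis=1)
    return PPGRecord(
        t=raw.t,
        signal=pd.DataFrame(out),
        sampling_rate_hz=raw.sampling_rate_hz,
        subject_id=raw.subject_id,
        drive_ma=raw.drive_ma,
    )


def downsample_dc(record: PPGRecord, window_s: float = DEFAULT_WINDOW_S) -> PPGRecord:
    """Reduce to quasi-DC by non-overlapping block means of ``window_s`` seconds.

    The output has one sample per window at the window center; a trailing
    partial window is dropped.
    """
    n_per = window_s * record.sampling_rate_hz
    if abs(n_per - round(n_per)) > 1e-9 or round(n_per) < 1:
        raise ValueError(
            f"window_s * sampling_rate must be a positive integer, got {n_per}"
        )
    n_per = int(round(n_per))
    n_blocks = record.n_samples // n_per
    if n_blocks == 0:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than one "
            f"{window_s:g}-s window ({n_per} samples)"
        )
    data = record.signal.to_numpy()[: n_blocks * n_per]
    means = data.reshape(n_blocks, n_per, data.shape[1]).mean(axis=1)
    t0 = record.t[0]
    t_out = t0 + (np.arange(n_blocks) + 0.5) * window_s
    return PPGRecord(
        t=t_out,
        signal=pd.DataFrame(means, columns=record.signal.columns),
        sampling_rate_hz=1.0 / window_s,
        subject_id=record.subject_id,
        drive_ma=record.drive_ma,
    )


def absorbance(i: np.ndarray | float, i0: np.ndarray | float) -> np.ndarray | float:
    """Beer-Lambert absorbance -ln(I / I0); both intensities must be positive."""
    i_arr = np.asarray(i, dtype=float)
    i0_arr = np.asarray(i0, dtype=float)
    if np.any(i0_arr <= 0):
        raise ValueError("reference intensity I0 must be strictly positive")
    if np.any(i_arr <= 0):
        bad = np.flatnonzero(np.atleast_1d(i_arr) <= 0)
        raise ValueError(
            f"nonpositive photocurrent at sample index(es) {bad[:10].tolist()}; "
            "absorbance undefined"
        )
    out = -np.log(i_arr / i0_arr)
    return float(out) if np.isscalar(i) and np.isscalar(i0) else out


def window_slopes(
    record: PPGRecord,
    calib: CalibrationTable,
    wavelength_subset: Sequence[int] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    nonpositive: str = "error",
) -> pd.DataFrame:
    """Per-window absorbance-vs-wavelength slopes m1 (PD1) and m2 (PD2).

    If the record is still at the raw sampling rate it is first reduced by
    :func:`downsample_dc`.  For each window and photodiode group, absorbance
    A(l) = -ln(I(l)/I0*(l)) is evaluated at each subset wavelength against
    the calibration at the record's drive current, and the OLS slope of A
    against wavelength (nm) is the feature.

    ``nonpositive``: ``"error"`` (default) refuses nonpositive quasi-DC
    intensities; ``"clip"`` substitutes the smallest positive value in the
    same channel and logs how often.
    """
    if nonpositive not in ("error", "clip"):
        raise ValueError("nonpositive must be 'error' or 'clip'")
    if abs(record.sampling_rate_hz - 1.0 / window_s) > 1e-12:
        record = downsample_dc(record, window_s=window_s)
    groups = record.pd_groups()
    wavelengths = record.wavelengths()
    subset = list(wavelength_subset) if wavelength_subset is not None else wavelengths
    if len(subset) < 2:
        raise ValueError("need at least two wavelengths for a slope")
    unknown = [wl for wl in subset if wl not in wavelengths]
    if unknown:
        raise ValueError(f"wavelengths {unknown} not present in record (has {wavelengths})")

    lam = np.asarray(subset, dtype=float)
    lam_c = lam - lam.mean()
    sxx = float((lam_c**2).sum())

    out: dict[str, np.ndarray] = {"t_center_s": record.t.copy()}
    for group in groups:
        a_cols = []
        for wl in subset:
            i0 = reference_intensity(calib, wl, group, record.drive_ma)
            col = record.signal[channel_name(wl, group)].to_numpy()
            if nonpositive == "clip" and np.any(col <= 0):
                floor = col[col > 0].min() if np.any(col > 0) else np.finfo(float).tiny
                n_bad = int((col <= 0).sum())
                logger.warning(
                    "channel %s: clipped %d nonpositive quasi-DC values to %g uA",
                    channel_name(wl, group), n_bad, floor,
                )
                col = np.where(col <= 0, floor, col)
            try:
                a_cols.append(absorbance(col, i0))
            except ValueError as exc:
                raise ValueError(f"channel {channel_name(wl, group)}: {exc}") from exc
        a = np.column_stack(a_cols)  # (n_windows, n_wavelengths)
        slopes = (a - a.mean(axis=1, keepdims=True)) @ lam_c / sxx
        key = {"pd1": "m1", "pd2": "m2"}.get(group, f"m_{group}")
        out[key] = slopes
    df = pd.DataFrame(out)
    if not np.all(np.isfinite(df.drop(columns="t_center_s").to_numpy())):
        raise ValueError("non-finite slope feature computed")
    return df


def build_feature_table(
    slopes: pd.DataFrame,
    subject_id: str,
    anthropometrics: Mapping[str, Mapping[str, float]],
    vo2_ref: VO2Trace | None = None,
    window_s: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Assemble one subject's per-window feature rows.

    Joins the slope features with the subject's height and weight and, when a
    reference trace is supplied, the mean reference VO2 over each window's
    half-open [start, end) interval.  Windows without any overlapping
    reference sample are dropped (the drop count is logged).
    """
    if subject_id not in anthropometrics:
        raise KeyError(f"no anthropometrics for subject {subject_id!r}")
    meta = anthropometrics[subject_id]
    df = slopes.copy()
    df.insert(0, "subject_id", subject_id)
    df["height_cm"] = float(meta["height_cm"])
    df["weight_kg"] = float(meta["weight_kg"])
    if vo2_ref is None:
        df["vo2_ref"] = np.nan
        return df.reset_index(drop=True)

    starts = df["t_center_s"].to_numpy() - window_s / 2.0
    targets = np.full(len(df), np.nan)
    for k, start in enumerate(starts):
        in_win = (vo2_ref.t >= start) & (vo2_ref.t < start + window_s)
        if np.any(in_win):
            targets[k] = vo2_ref.vo2[in_win].mean()
    df["vo2_ref"] = targets
    n_dropped = int(np.isnan(targets).sum())
    if n_dropped:
        logger.info(
            "subject %s: dropped %d of %d windows with no reference VO2 sample",
            subject_id, n_dropped, len(df),
        )
    return df[~np.isnan(targets)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# File formats (delimited text + JSON metadata)

def write_ppg_csv(record: PPGRecord, path: str | Path) -> None:
    df = record.signal.copy()
    df.insert(0, "time_s", record.t)
    df.to_csv(path, index=False, float_format="%.10g")


def read_ppg_csv(
    path: str | Path, sampling_rate_hz: float | None = None,
    subject_id: str = "", drive_ma: float = 50.0,
) -> PPGRecord:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing mandatory 'time_s' column")
    t = df["time_s"].to_numpy(float)
    if sampling_rate_hz is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from {t.size} samples")
        sampling_rate_hz = 1.0 / (t[1] - t[0])
    return PPGRecord(
        t=t,
        signal=df.drop(columns="time_s"),
        sampling_rate_hz=float(sampling_rate_hz),
        subject_id=subject_id,
        drive_ma=drive_ma,
    )


def write_vo2_csv(trace: VO2Trace, path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.t, "vo2_ml_kg_min": trace.vo2}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_vo2_csv(path: str | Path) -> VO2Trace:
    df = pd.read_csv(path)
    return VO2Trace(t=df["t_s"].to_numpy(float), vo2=df["vo2_ml_kg_min"].to_numpy(float))


def write_subjects_json(
    anthropometrics: Mapping[str, Mapping[str, float]], path: str | Path
) -> None:
    Path(path).write_text(json.dumps(dict(anthropometrics), indent=1), encoding="utf-8")


def read_subjects_json(path: str | Path) -> dict[str, dict[str, float]]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    for sid, meta in data.items():
        for key in ("height_cm", "weight_kg"):
            if key not in meta:
                raise ValueError(f"subject {sid!r}: missing {key}")
    return data
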