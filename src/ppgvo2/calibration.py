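"""White-card calibration: reference intensity I0* versus LED drive current.

Incident intensity cannot be measured in situ, so the device is calibrated
against a reflective white card: for each channel (wavelength x photodiode
group) the photodiode current I0* is recorded while the LED pulse amplitude
is swept from 10 to 90 mA.  The pipeline treats I0* as the incident-intensity
denominator of the Beer-Lambert absorbance (the I0 ~ I0* approximation), and
operates at a single 50 mA drive point; values between tabulated drive levels
are linearly interpolated, and no extrapolation outside the swept range is
permitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import DEVICE_WAVELENGTHS_NM

__all__ = [
    "PD_GROUPS",
    "OPERATING_CURRENT_MA",
    "CalibrationTable",
    "load_calibration",
    "save_calibration",
    "make_default_calibration",
]

logger = logging.getLogger(__name__)

PD_GROUPS: tuple[str, ...] = ("pd1", "pd2")

#: LED pulse amplitude used for all wavelengths during data collection.
OPERATING_CURRENT_MA: float = 50.0

_DRIVE_MIN_MA = 10.0
_DRIVE_MAX_MA = 90.0


@dataclass
class CalibrationTable:
    """Per-channel lookup from LED drive current (mA) to I0* photocurrent (uA).

    ``i0_star`` maps ``(wavelength_nm, pd_group)`` to an array of reference
    photocurrents, one per entry of ``drive_levels_ma``.
    """

    drive_levels_ma: np.ndarray
    i0_star: dict[tuple[int, str], np.ndarray]
    operating_current_ma: float = OPERATING_CURRENT_MA

    def __post_init__(self) -> None:
        self.drive_levels_ma = np.asarray(self.drive_levels_ma, dtype=float)
        d = self.drive_levels_ma
        if d.ndim != 1 or d.size < 2:
            raise ValueError("drive_levels_ma must be a 1-D array with >= 2 levels")
        if np.any(np.diff(d) <= 0):
            raise ValueError("drive levels must be strictly ascending")
        if d[0] > _DRIVE_MIN_MA or d[-1] < _DRIVE_MAX_MA:
            raise ValueError(
                f"drive levels must cover [{_DRIVE_MIN_MA:g}, {_DRIVE_MAX_MA:g}] mA, "
                f"got [{d[0]:g}, {d[-1]:g}]"
            )
        clean: dict[tuple[int, str], np.ndarray] = {}
        for key, vals in self.i0_star.items():
            wl, group = key
            v = np.asarray(vals, dtype=float)
            if v.shape != d.shape:
                raise ValueError(f"channel {key}: expected {d.size} values, got {v.size}")
            if np.any(v <= 0):
                raise ValueError(f"channel {key}: I0* must be strictly positive")
            if np.any(np.diff(v) < 0):
                # LED output should grow with drive; accept but flag.
                logger.warning("channel %s: I0* not monotone in drive current", key)
            clean[(int(wl), str(group))] = v
        self.i0_star = clean

    @property
    def channels(self) -> list[tuple[int, str]]:
        return sorted(self.i0_star.keys())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CalibrationTable):
            return NotImplemented
        return (
            np.array_equal(self.drive_levels_ma, other.drive_levels_ma)
            and self.operating_current_ma == other.operating_current_ma
            and self.channels == other.channels
            and all(np.array_equal(self.i0_star[k], other.i0_star[k]) for k in self.i0_star)
        )


def reference_intensity(
    table: CalibrationTable,
    wavelength_nm: int,
    pd_group: str,
    drive_ma: float | None = None,
) -> float:
    """I0* (uA) for one channel at a drive current.

    Exact at tabulated drive levels, linearly interpolated between them;
    drive currents outside the swept [10, 90] mA range are refused rather
    than extrapolated.  ``drive_ma`` defaults to the table's operating point.
    """
    if drive_ma is None:
        drive_ma = table.operating_current_ma
    key = (int(wavelength_nm), str(pd_group))
    if key not in table.i0_star:
        raise KeyError(
            f"unknown calibration channel (wavelength={wavelength_nm} nm, pd_group={pd_group!r})"
        )
    if not _DRIVE_MIN_MA <= drive_ma <= _DRIVE_MAX_MA:
        raise ValueError(
            f"drive current {drive_ma} mA outside calibrated range "
            f"[{_DRIVE_MIN_MA:g}, {_DRIVE_MAX_MA:g}] mA"
        )
    return float(np.interp(drive_ma, table.drive_levels_ma, table.i0_star[key]))


def save_calibration(table: CalibrationTable, path: str | Path) -> None:
    """Write a calibration table as JSON (schema: drive levels + per-channel I0*)."""
    payload = {
        "drive_levels_ma": table.drive_levels_ma.tolist(),
        "operating_current_ma": table.operating_current_ma,
        "channels": [
            {
                "wavelength_nm": wl,
                "pd_group": group,
                "i0_star_ua": table.i0_star[(wl, group)].tolist(),
            }
            for wl, group in table.channels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_calibration(path: str | Path) -> CalibrationTable:
    """Load and validate a JSON calibration table; round-trips losslessly."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed calibration file {path}: {exc}") from exc
    try:
        drive = payload["drive_levels_ma"]
        channels = payload["channels"]
        i0 = {
            (int(ch["wavelength_nm"]), str(ch["pd_group"])): np.asarray(
                ch["i0_star_ua"], dtype=float
            )
            for ch in channels
        }
        op = float(payload.get("operating_current_ma", OPERATING_CURRENT_MA))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"calibration file {path} missing field: {exc}") from exc
    return CalibrationTable(drive_levels_ma=np.asarray(drive, float), i0_star=i0, operating_current_ma=op)


def validate_channels(
    table: CalibrationTable,
    wavelengths_nm: tuple[int, ...] = DEVICE_WAVELENGTHS_NM,
    pd_groups: tuple[str, ...] = PD_GROUPS,
) -> None:
    """Raise if the table does not cover every wavelength x PD-group channel."""
    missing = [
        (wl, g)
        for wl in wavelengths_nm
        for g in pd_groups
        if (wl, g) not in table.i0_star
    ]
    if missing:
        raise ValueError(f"calibration table missing channels: {missing}")


def make_default_calibration(seed: int = 0) -> CalibrationTable:
    """A plausible white-card calibration, reproducible from ``seed``.

    Each channel gets a monotone, saturating drive-response curve
    I0*(d) = Imax * (1 - exp(-d / d0)) with a seeded per-channel scale, the
    shape the white-card sweep exhibits (LED output compresses at high
    drive).  Shorter wavelengths are given somewhat higher photocurrents and
    the vertically combined photodiode group (pd2) collects slightly less
    light than the horizontal one (pd1).
    """
    rng = np.random.default_rng(seed)
    drive = np.arange(10.0, 91.0, 10.0)
    base_scale_ua = {670: 60.0, 770: 55.0, 810: 52.0, 850: 48.0, 950: 40.0}
    group_gain = {"pd1": 1.0, "pd2": 0.88}
    i0: dict[tuple[int, str], np.ndarray] = {}
    for wl in DEVICE_WAVELENGTHS_NM:
        for group in PD_GROUPS:
            imax = base_scale_ua[wl] * group_gain[group] * rng.uniform(0.9, 1.1)
            d0 = rng.uniform(40.0, 55.0)
            i0[(wl, group)] = imax * (1.0 - np.exp(-drive / d0))
    return CalibrationTable(drive_levels_ma=drive, i0_star=i0)
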