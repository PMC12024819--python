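"""Synthetic exercise cohort: treadmill VO2 kinetics and a Beer-Lambert PPG forward model.

Emulates an 8-subject graded treadmill session (a modified Bruce-style
protocol: 0.5 min sitting, 2 min at 1.5 mph, 2 min at 2.5 mph, 1 min at
4 mph, 3 min at 6 mph).  Each subject's oxygen uptake follows first-order
(mono-exponential) kinetics toward a stage-dependent steady-state demand
that is linear in treadmill speed; tissue oxygen saturation falls linearly
with VO2 above rest; and raw 100 Hz photocurrents are produced by the same
Beer-Lambert law the feature pipeline inverts,

    I(l) = I0*(l) * exp(-eps_mix(s, l) * c_tot * path(l))
           * (1 + AC ripple at the heart rate) * (1 + sensor noise),

with additive motion-artifact bursts during running stages and independent
noise draws for the two photodiode groups.  Reference VO2 is emitted at
breath-like irregular intervals with multiplicative measurement noise,
mimicking a breath-by-breath metabolic cart.

Everything is reproducible from a single seed.  The coupling constants
(saturation drop per unit VO2, hemoglobin concentration, optical pathlength)
are generator conventions chosen to give the slope features a realistic
dynamic range; they are not physiological claims.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .calibration import (
    CalibrationTable,
    make_default_calibration,
    reference_intensity,
    validate_channels,
)
from .features import (
    PPGRecord,
    VO2Trace,
    channel_name,
    write_ppg_csv,
    write_subjects_json,
    write_vo2_csv,
)
from .spectra import DEVICE_WAVELENGTHS_NM, ExtinctionSpectrum, default_spectrum

__all__ = [
    "ProtocolStage",
    "ProtocolSpec",
    "DEFAULT_PROTOCOL",
    "SubjectParams",
    "MotionParams",
    "DEFAULT_POPULATION",
    "CohortMember",
    "vo2_trajectory",
    "saturation_from_vo2",
    "generate_ppg",
    "generate_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtocolStage:
    label: str
    duration_s: float
    speed_mph: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("stage duration must be positive")
        if self.speed_mph < 0:
            raise ValueError("stage speed must be nonnegative")


@dataclass(frozen=True)
class ProtocolSpec:
    stages: tuple[ProtocolStage, ...]

    @property
    def total_duration_s(self) -> float:
        return sum(st.duration_s for st in self.stages)

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        """Treadmill speed (mph) at each time; last stage extends to the end."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([st.duration_s for st in self.stages])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(self.stages) - 1)
        speeds = np.array([st.speed_mph for st in self.stages])
        return speeds[idx]


#: The graded treadmill session driving the simulator (510 s = 51 windows).
DEFAULT_PROTOCOL = ProtocolSpec(
    stages=(
        ProtocolStage("sitting", 30.0, 0.0),
        ProtocolStage("walk_1", 120.0, 1.5),
        ProtocolStage("walk_2", 120.0, 2.5),
        ProtocolStage("run_1", 60.0, 4.0),
        ProtocolStage("run_2", 180.0, 6.0),
    )
)

#: Treadmill speed at or above which motion-artifact bursts are active.
MOTION_SPEED_THRESHOLD_MPH = 4.0


@dataclass(frozen=True)
class MotionParams:
    """Additive motion-burst model: Poisson arrivals, exponential amplitudes."""

    rate_per_s: float = 0.1
    amplitude_frac: float = 0.05  # exponential scale, as a fraction of I0*
    decay_s: float = 0.2


@dataclass(frozen=True)
class SubjectParams:
    """Physiological and optical parameters of one simulated subject."""

    subject_id: str = "s01"
    height_cm: float = 172.0
    weight_kg: float = 72.0
    vo2_rest: float = 3.5            # mL/kg/min at rest (~1 MET)
    vo2_per_speed: float = 3.7       # demand slope, mL/kg/min per mph
    tau_s: float = 30.0              # first-order VO2 time constant
    s_rest: float = 0.85             # resting tissue saturation fraction
    k_sat: float = 0.012             # saturation drop per mL/kg/min above rest
    c_tot: float = 2.3e-3            # total hemoglobin concentration, M
    pathlength_cm: float | Mapping[int, float] = 0.3
    ac_amplitude_frac: float = 0.01  # cardiac ripple, fraction of DC
    hr_rest: float = 65.0
    hr_max: float = 185.0
    noise_frac: float = 0.02         # multiplicative sensor noise SD
    motion: MotionParams = MotionParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.s_rest <= 1.0:
            raise ValueError("s_rest must be in (0, 1]")
        for name in ("vo2_rest", "tau_s", "c_tot", "height_cm", "weight_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def pathlength(self, wavelength_nm: int) -> float:
        if isinstance(self.pathlength_cm, Mapping):
            return float(self.pathlength_cm[wavelength_nm])
        return float(self.pathlength_cm)


#: Uniform ranges the cohort generator draws per-subject parameters from.
DEFAULT_POPULATION: dict[str, tuple[float, float]] = {
    "height_cm": (155.0, 190.0),
    "weight_kg": (50.0, 95.0),
    "vo2_per_speed": (3.2, 4.2),
    "tau_s": (25.0, 35.0),
    "s_rest": (0.80, 0.90),
    "k_sat": (0.010, 0.014),
    "c_tot": (2.0e-3, 2.6e-3),
    "pathlength_cm": (0.25, 0.35),
    "hr_rest": (55.0, 75.0),
    "hr_max": (175.0, 195.0),
}

#: Multiplicative noise SD of the breath-by-breath reference measurement.
BREATH_NOISE_FRAC = 0.05
BREATH_INTERVAL_S = (2.0, 4.0)


def vo2_trajectory(
    protocol: ProtocolSpec, subject: SubjectParams, dt_s: float = 0.1
) -> VO2Trace:
    """First-order VO2 kinetics along the protocol, sampled every ``dt_s``.

    Stage demand is V* = vo2_rest + vo2_per_speed * speed and V relaxes
    toward it as dV/dt = (V* - V)/tau, integrated with the exact exponential
    update per step from V(0) = vo2_rest.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, protocol.total_duration_s, dt_s)
    targets = subject.vo2_rest + subject.vo2_per_speed * protocol.speed_at(t)
    decay = np.exp(-dt_s / subject.tau_s) if subject.tau_s > 0 else 0.0
    v = np.empty_like(t)
    v[0] = subject.vo2_rest
    for k in range(1, t.size):
        v[k] = targets[k - 1] + (v[k - 1] - targets[k - 1]) * decay
    return VO2Trace(t=t, vo2=v)


def saturation_from_vo2(v: np.ndarray | float, subject: SubjectParams) -> np.ndarray | float:
    """Tissue saturation: linear drop below s_rest as VO2 rises, clipped to [0.2, 1]."""
    s = subject.s_rest - subject.k_sat * (np.asarray(v, dtype=float) - subject.vo2_rest)
    out = np.clip(s, 0.2, 1.0)
    return float(out) if np.isscalar(v) else out


def _heart_rate(v: np.ndarray, subject: SubjectParams, v_span: float = 30.0) -> np.ndarray:
    frac = np.clip((v - subject.vo2_rest) / (v_span - subject.vo2_rest), 0.0, 1.0)
    return subject.hr_rest + (subject.hr_max - subject.hr_rest) * frac


def _motion_bursts(
    t: np.ndarray, active: np.ndarray, params: MotionParams, rng: np.random.Generator
) -> np.ndarray:
    """Unit-scale additive burst waveform (multiplied by I0* per channel later)."""
    out = np.zeros_like(t)
    if params.rate_per_s <= 0 or not np.any(active):
        return out
    duration = t[-1] - t[0] if t.size > 1 else 0.0
    n_events = rng.poisson(params.rate_per_s * duration)
    if n_events == 0:
        return out
    starts = rng.uniform(t[0], t[-1], size=n_events)
    amps = rng.exponential(params.amplitude_frac, size=n_events)
    for t0, amp in zip(starts, amps):
        i0 = np.searchsorted(t, t0)
        span = int(5 * params.decay_s * (t.size / max(duration, 1e-9)))
        sl = slice(i0, min(i0 + max(span, 1), t.size))
        out[sl] += amp * np.exp(-(t[sl] - t0) / params.decay_s)
    return out * active


def generate_ppg(
    vo2: VO2Trace,
    subject: SubjectParams,
    calib: CalibrationTable,
    spectrum: ExtinctionSpectrum | None = None,
    rate_hz: float = 100.0,
    protocol: ProtocolSpec | None = None,
) -> PPGRecord:
    """Raw multiwavelength photocurrents from the Beer-Lambert forward model.

    The dense VO2 trace is interpolated to the PPG sampling grid, mapped to
    tissue saturation, and attenuated through each channel's extinction
    mixture; cardiac ripple, multiplicative sensor noise (independent per
    photodiode group) and — when a protocol is supplied — motion bursts
    during running stages are layered on top.  Nonpositive intensities are
    clipped to machine epsilon and logged.
    """
    spectrum = spectrum if spectrum is not None else default_spectrum()
    validate_channels(calib, tuple(spectrum.wavelengths_nm))
    # Sample the full duration the dense trace covers (its last step included),
    # holding the final VO2 value over the trailing sub-step.
    dt_ref = vo2.t[1] - vo2.t[0] if vo2.t.size > 1 else 1.0 / rate_hz
    duration = vo2.t[-1] - vo2.t[0] + dt_ref
    n = int(round(duration * rate_hz))
    t = vo2.t[0] + np.arange(n) / rate_hz
    v = np.interp(t, vo2.t, vo2.vo2)
    s = saturation_from_vo2(v, subject)

    hr = _heart_rate(v, subject)
    phase = np.cumsum(hr / 60.0) / rate_hz
    ripple = subject.ac_amplitude_frac * np.sin(2.0 * np.pi * phase)

    if protocol is not None:
        active = (protocol.speed_at(t) >= MOTION_SPEED_THRESHOLD_MPH).astype(float)
    else:
        active = np.zeros_like(t)

    ss = np.random.SeedSequence(subject.seed)
    rng_noise = {g: np.random.default_rng(c) for g, c in zip(("pd1", "pd2"), ss.spawn(2))}
    rng_motion = np.random.default_rng(ss.spawn(1)[0])
    burst = _motion_bursts(t, active, subject.motion, rng_motion)

    cols: dict[str, np.ndarray] = {}
    n_clipped = 0
    for wl in spectrum.wavelengths_nm:
        i_wl = spectrum.index(wl)
        eps_mix = s * spectrum.eps_hbo2[i_wl] + (1.0 - s) * spectrum.eps_hb[i_wl]
        attenuation = np.exp(-eps_mix * subject.c_tot * subject.pathlength(wl))
        for group in ("pd1", "pd2"):
            i0 = reference_intensity(calib, wl, group)
            noise = rng_noise[group].normal(0.0, subject.noise_frac, size=t.size) \
                if subject.noise_frac > 0 else 0.0
            sig = i0 * attenuation * (1.0 + ripple) * (1.0 + noise) + i0 * burst
            bad = sig <= 0
            if np.any(bad):
                n_clipped += int(bad.sum())
                sig = np.where(bad, np.finfo(float).eps, sig)
            cols[channel_name(wl, group)] = sig
    if n_clipped:
        logger.warning("subject %s: clipped %d nonpositive samples", subject.subject_id, n_clipped)
    return PPGRecord(
        t=t,
        signal=pd.DataFrame(cols),
        sampling_rate_hz=rate_hz,
        subject_id=subject.subject_id,
        drive_ma=calib.operating_current_ma,
    )


@dataclass
class CohortMember:
    record: PPGRecord
    vo2_ref: VO2Trace
    subject: SubjectParams

    @property
    def meta(self) -> dict[str, float]:
        return {"height_cm": self.subject.height_cm, "weight_kg": self.subject.weight_kg}


def _breath_reference(
    vo2: VO2Trace, rng: np.random.Generator, noise_frac: float = BREATH_NOISE_FRAC
) -> VO2Trace:
    """Irregular breath-by-breath sampling of the dense trace with noise."""
    times = []
    t = float(rng.uniform(*BREATH_INTERVAL_S))
    while t < vo2.t[-1]:
        times.append(t)
        t += float(rng.uniform(*BREATH_INTERVAL_S))
    times = np.asarray(times)
    values = np.interp(times, vo2.t, vo2.vo2)
    values = values * (1.0 + rng.normal(0.0, noise_frac, size=values.size))
    values = np.maximum(values, 1e-6)
    return VO2Trace(t=times, vo2=values)


def generate_cohort(
    n_subjects: int = 8,
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    seed: int = 0,
    population: Mapping[str, tuple[float, float]] | None = None,
    calib: CalibrationTable | None = None,
    spectrum: ExtinctionSpectrum | None = None,
    rate_hz: float = 100.0,
    noise: bool = True,
) -> list[CohortMember]:
    """Simulate a cohort: per-subject parameter draws, PPG and breath reference.

    ``noise=False`` disables sensor noise, cardiac ripple, motion bursts and
    reference noise, leaving the pure Beer-Lambert forward model (used by
    consistency tests).  Deterministic for a given seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    population = dict(DEFAULT_POPULATION if population is None else population)
    calib = calib if calib is not None else make_default_calibration(derive_seed(seed, "calibration"))
    spectrum = spectrum if spectrum is not None else default_spectrum()
    members: list[CohortMember] = []
    for k in range(n_subjects):
        sid = f"s{k + 1:02d}"
        rng = np.random.default_rng(derive_seed(seed, f"subject:{sid}"))
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in population.items()}
        subject = SubjectParams(
            subject_id=sid,
            seed=derive_seed(seed, f"ppg:{sid}"),
            **draws,
        )
        if not noise:
            subject = dataclasses.replace(
                subject,
                noise_frac=0.0,
                ac_amplitude_frac=0.0,
                motion=MotionParams(rate_per_s=0.0),
            )
        dense = vo2_trajectory(protocol, subject)
        record = generate_ppg(dense, subject, calib, spectrum, rate_hz=rate_hz, protocol=protocol)
        breath_rng = np.random.default_rng(derive_seed(seed, f"breath:{sid}"))
        ref = _breath_reference(
            dense, breath_rng, noise_frac=BREATH_NOISE_FRAC if noise else 0.0
        )
        members.append(CohortMember(record=record, vo2_ref=ref, subject=subject))
    return members


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(
    members: Sequence[CohortMember],
    outdir: str | Path,
    calib: CalibrationTable | None = None,
    seed: int | None = None,
) -> Path:
    """Write a cohort directory (PPG/VO2 CSVs, subject JSON, manifest) and
    return the manifest path."""
    from .calibration import save_calibration

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    anthropometrics = {}
    params = {}
    for m in members:
        sid = m.subject.subject_id
        ppg_path = outdir / f"{sid}_ppg.csv"
        vo2_path = outdir / f"{sid}_vo2.csv"
        write_ppg_csv(m.record, ppg_path)
        write_vo2_csv(m.vo2_ref, vo2_path)
        files += [ppg_path.name, vo2_path.name]
        anthropometrics[sid] = m.meta
        p = dataclasses.asdict(m.subject)
        p["motion"] = dataclasses.asdict(m.subject.motion)
        params[sid] = p
    write_subjects_json(anthropometrics, outdir / "subjects.json")
    files.append("subjects.json")
    if calib is not None:
        save_calibration(calib, outdir / "calibration.json")
        files.append("calibration.json")
    manifest = {
        "seed": seed,
        "n_subjects": len(members),
        "subject_params": params,
        "files": {name: _file_sha256(outdir / name) for name in sorted(files)},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    logger.info("wrote cohort of %d subjects to %s", len(members), outdir)
    return manifest_path
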