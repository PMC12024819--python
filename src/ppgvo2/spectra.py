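"""Hemoglobin extinction spectra and the isosbestic-anchored slope theory.

The VO2 estimator rests on a simple spectroscopic observation: the molar
extinction coefficients of deoxy-hemoglobin (Hb) and oxy-hemoglobin (HbO2)
cross at the isosbestic point near 810 nm, so a linear fit of blood's mixed
extinction coefficient against wavelength has a slope that changes sign and
magnitude with oxygen saturation.  After rescaling every wavelength's
coefficient so that all saturation-mixture lines pass exactly through the
810 nm pivot, that slope becomes an exactly affine, antisymmetric function of
saturation — the quantity the absorbance-slope features downstream estimate
from tissue.

Coefficients are stored in the conventional base-10 tabulation
(cm^-1 M^-1) in a packaged data file and converted to the natural-log
convention (x ln 10) at load, matching the exponential form of the
Beer-Lambert law used throughout the package.  The tabulated Hb and HbO2
values at 810 nm differ slightly; both are replaced by their mean so the
isosbestic pivot is exact and the affine slope law holds to machine
precision.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "DEVICE_WAVELENGTHS_NM",
    "ISOSBESTIC_NM",
    "ExtinctionSpectrum",
    "ScaledSpectrum",
    "default_spectrum",
    "mixture_coefficient",
    "compute_alpha",
    "fit_wavelength_slope",
    "saturation_slope",
]

#: The five nominal LED wavelengths of the wrist device.
DEVICE_WAVELENGTHS_NM: tuple[int, ...] = (670, 770, 810, 850, 950)

#: Wavelength at which Hb and HbO2 extinction coefficients are equal.
ISOSBESTIC_NM: int = 810

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Molar extinction coefficients of Hb and HbO2 at a set of wavelengths.

    Coefficients are in cm^-1 M^-1 under the natural-log (base-e)
    convention.  The isosbestic wavelength (810 nm) must be present and its
    two coefficients must be exactly equal.
    """

    wavelengths_nm: tuple[int, ...]
    eps_hb: tuple[float, ...]
    eps_hbo2: tuple[float, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        wl = self.wavelengths_nm
        if len(wl) != len(self.eps_hb) or len(wl) != len(self.eps_hbo2):
            raise ValueError("wavelengths and coefficient lists must have equal length")
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("wavelengths must be strictly ascending")
        if any(e <= 0 for e in self.eps_hb) or any(e <= 0 for e in self.eps_hbo2):
            raise ValueError("extinction coefficients must be strictly positive")
        if ISOSBESTIC_NM not in wl:
            raise ValueError(f"spectrum must include the {ISOSBESTIC_NM} nm isosbestic point")
        i = wl.index(ISOSBESTIC_NM)
        if self.eps_hb[i] != self.eps_hbo2[i]:
            raise ValueError(
                f"eps_hb and eps_hbo2 must be exactly equal at {ISOSBESTIC_NM} nm "
                f"(got {self.eps_hb[i]} vs {self.eps_hbo2[i]})"
            )

    def index(self, wavelength_nm: int) -> int:
        try:
            return self.wavelengths_nm.index(wavelength_nm)
        except ValueError:
            raise KeyError(
                f"wavelength {wavelength_nm} nm not in spectrum {self.wavelengths_nm}"
            ) from None

    def mean_coefficient(self, wavelength_nm: int) -> float:
        """(eps_hb + eps_hbo2) / 2 at one wavelength — the s=0.5 mixture."""
        i = self.index(wavelength_nm)
        return 0.5 * (self.eps_hb[i] + self.eps_hbo2[i])


@dataclass(frozen=True)
class ScaledSpectrum:
    """An :class:`ExtinctionSpectrum` with per-wavelength scaling alpha(lambda).

    alpha is constructed so every saturation-mixture line passes exactly
    through the 810 nm pivot: alpha(l) = eps_mean(810) / eps_mean(l), hence
    alpha(810) = 1 and alpha(l) * eps_mean(l) is the same constant at every
    wavelength.
    """

    base: ExtinctionSpectrum
    alpha: tuple[float, ...]
    scaled_eps_hb: tuple[float, ...] = field(init=False)
    scaled_eps_hbo2: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.base.wavelengths_nm):
            raise ValueError("alpha must have one entry per wavelength")
        i810 = self.base.index(ISOSBESTIC_NM)
        if self.alpha[i810] != 1.0:
            raise ValueError("alpha must be exactly 1 at the isosbestic wavelength")
        object.__setattr__(
            self,
            "scaled_eps_hb",
            tuple(a * e for a, e in zip(self.alpha, self.base.eps_hb)),
        )
        object.__setattr__(
            self,
            "scaled_eps_hbo2",
            tuple(a * e for a, e in zip(self.alpha, self.base.eps_hbo2)),
        )

    @property
    def pivot_value(self) -> float:
        """The common value alpha(l)*eps_mean(l), equal to eps_mean(810)."""
        return self.base.mean_coefficient(ISOSBESTIC_NM)


def _load_packaged_table() -> tuple[tuple[int, ...], tuple[float, ...], tuple[float, ...]]:
    path = resources.files("ppgvo2.data").joinpath("extinction_base10.csv")
    wavelengths: list[int] = []
    hb: list[float] = []
    hbo2: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            wavelengths.append(int(row["wavelength_nm"]))
            hb.append(float(row["eps_hb"]))
            hbo2.append(float(row["eps_hbo2"]))
    return tuple(wavelengths), tuple(hb), tuple(hbo2)


def default_spectrum() -> ExtinctionSpectrum:
    """Load the packaged five-wavelength spectrum.

    Base-10 tabulated values are converted to the natural-log convention and
    the 810 nm pair is replaced by its mean to enforce an exact isosbestic
    point.
    """
    wl, hb10, hbo10 = _load_packaged_table()
    hb = [e * _LN10 for e in hb10]
    hbo2 = [e * _LN10 for e in hbo10]
    i = wl.index(ISOSBESTIC_NM)
    iso = 0.5 * (hb[i] + hbo2[i])
    hb[i] = iso
    hbo2[i] = iso
    return ExtinctionSpectrum(
        wavelengths_nm=wl,
        eps_hb=tuple(hb),
        eps_hbo2=tuple(hbo2),
        source_note=(
            "Packaged compilation values (base-10, cm^-1 M^-1) converted to the "
            "natural-log convention; 810 nm pair symmetrized to its mean."
        ),
    )


def mixture_coefficient(
    spectrum: ExtinctionSpectrum, s: float, wavelength_nm: int
) -> float:
    """Extinction coefficient of blood at oxygen saturation ``s``.

    Linear mixture s*eps_hbo2 + (1-s)*eps_hb; the interpolation between the
    fully deoxygenated (s=0) and fully oxygenated (s=1) endpoints.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"saturation must be in [0, 1], got {s}")
    i = spectrum.index(wavelength_nm)
    return s * spectrum.eps_hbo2[i] + (1.0 - s) * spectrum.eps_hb[i]


def compute_alpha(spectrum: ExtinctionSpectrum) -> ScaledSpectrum:
    """Construct the isosbestic-pivot scaling alpha(l) = eps_mean(810)/eps_mean(l)."""
    pivot = spectrum.mean_coefficient(ISOSBESTIC_NM)
    alpha = []
    for wl in spectrum.wavelengths_nm:
        m = spectrum.mean_coefficient(wl)
        if m == 0:
            raise ValueError(f"degenerate spectrum: mean coefficient is zero at {wl} nm")
        alpha.append(pivot / m)
    return ScaledSpectrum(base=spectrum, alpha=tuple(alpha))


def fit_wavelength_slope(
    xs: Sequence[float], ys: Sequence[float]
) -> tuple[float, float]:
    """Ordinary-least-squares slope and intercept of ``ys`` against ``xs``.

    The single regression primitive shared by the spectral theory and the
    per-window absorbance features.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} abscissae vs {y.shape[0]} ordinates")
    if x.size < 2:
        raise ValueError("need at least two points for a slope")
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate regression: all abscissae identical")
    ym = y.mean()
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = float(ym - slope * xm)
    return slope, intercept


def saturation_slope(
    scaled: ScaledSpectrum,
    s: float,
    wavelength_subset: Sequence[int] | None = None,
) -> float:
    """OLS slope of the alpha-scaled mixture coefficient against wavelength.

    By the pivot construction this slope is exactly affine in ``s``:
    zero at s=0.5 and antisymmetric about it.  Units: extinction per nm.
    """
    base = scaled.base
    subset = tuple(wavelength_subset) if wavelength_subset is not None else base.wavelengths_nm
    if len(subset) < 2:
        raise ValueError("wavelength subset must contain at least two wavelengths")
    ys = []
    for wl in subset:
        i = base.index(wl)
        ys.append(scaled.alpha[i] * mixture_coefficient(base, s, wl))
    slope, _ = fit_wavelength_slope([float(w) for w in subset], ys)
    return slope
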