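"""Albumin quantification from intrinsic tryptophan fluorescence.

Serum albumin excited at 280 nm emits around 345 nm.  Concentration is
read off a linear calibration curve (ordinary least squares, intercept
free) of peak intensity against known standards, valid over the linear
detection range 0.125–2 mg/ml; sample predictions outside that range are
flagged as extrapolated.  Triplicate intensities are averaged before
inversion, and concentrations may be normalised to the 1 mg/ml standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "CalibrationCurve",
    "CalibrationError",
    "peak_intensity",
    "fit_calibration",
    "predict_concentration",
    "normalize_to_standard",
    "EMISSION_GRID_NM",
    "PEAK_WAVELENGTH_NM",
]

#: Emission scan grid: 290–450 nm at 10 nm intervals (excitation 280 nm).
EMISSION_GRID_NM = np.arange(290.0, 451.0, 10.0)
PEAK_WAVELENGTH_NM = 345.0


class CalibrationError(ValueError):
    """Raised for unusable calibration input or an invalid fitted curve."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission scan (wavelength nm, intensity a.u.)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float = 280.0
    replicate_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        iy = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", iy)
        if wl.shape != iy.shape or wl.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length vectors")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(iy < 0):
            raise ValueError("intensities must be >= 0")


def peak_intensity(spectrum: EmissionSpectrum, wavelength_nm: float = PEAK_WAVELENGTH_NM,
                   mode: str = "nearest") -> float:
    """Intensity at the grid node nearest the requested wavelength.

    The emission grid is 10 nm so 345 nm falls between nodes; ties break
    toward the longer wavelength (the documented rule).  ``mode="parabolic"``
    instead fits a local parabola through the nearest node and its
    neighbours and evaluates it at the requested wavelength.
    """
    wl = spectrum.wavelengths_nm
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise KeyError(f"wavelength {wavelength_nm} nm outside spectral range "
                       f"[{wl[0]}, {wl[-1]}] nm")
    dist = np.abs(wl - wavelength_nm)
    best = np.flatnonzero(dist == dist.min())
    idx = int(best[-1])  # tie -> longer wavelength
    if mode == "nearest":
        return float(spectrum.intensities[idx])
    if mode == "parabolic":
        if not (0 < idx < wl.size - 1):
            return float(spectrum.intensities[idx])
        x = wl[idx - 1 : idx + 2]
        y = spectrum.intensities[idx - 1 : idx + 2]
        coeffs = np.polyfit(x - wl[idx], y, 2)
        return float(np.polyval(coeffs, wavelength_nm - wl[idx]))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map intensity = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    range_low_mg_ml: float = 0.125
    range_high_mg_ml: float = 2.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.range_low_mg_ml >= self.range_high_mg_ml:
            raise ValueError("range_low must be < range_high")


def fit_calibration(
    standards: Iterable[tuple[float, float]],
    range_low_mg_ml: float = 0.125,
    range_high_mg_ml: float = 2.0,
) -> CalibrationCurve:
    """Ordinary least squares of intensity on concentration, intercept free.

    ``standards`` is a sequence of (concentration mg/ml, intensity) pairs;
    at least 3 distinct concentrations are required.
    """
    pairs = np.asarray(list(standards), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise CalibrationError("need at least 3 (concentration, intensity) standards")
    conc, inten = pairs[:, 0], pairs[:, 1]
    if np.unique(conc).size < 3:
        raise CalibrationError("need at least 3 distinct concentrations")
    if np.ptp(conc) == 0:
        raise CalibrationError("zero variance in concentrations")
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), res, *_ = np.linalg.lstsq(design, inten, rcond=None)
    fitted = slope * conc + intercept
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    ss_res = float(np.sum((inten - fitted) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        range_low_mg_ml=range_low_mg_ml,
        range_high_mg_ml=range_high_mg_ml,
        n_points=int(pairs.shape[0]),
    )


@dataclass(frozen=True)
class ConcentrationResult:
    concentration_mg_ml: float
    in_range: bool
    mean_intensity: float


def predict_concentration(
    curve: CalibrationCurve,
    intensity: float | None = None,
    replicate_intensities: Sequence[float] | None = None,
) -> ConcentrationResult:
    """Invert the calibration line: (mean intensity - intercept) / slope.

    Triplicate (or any replicate) intensities are averaged first.  The
    result carries an ``in_range`` flag; predictions outside the linear
    detection range are extrapolations, not measurements.
    """
    if curve.slope <= 0:
        raise CalibrationError("calibration slope must be > 0 for inversion")
    if replicate_intensities is not None:
        reps = np.asarray(replicate_intensities, dtype=float)
        if reps.size == 0:
            raise ValueError("replicate_intensities must be non-empty")
        mean_int = float(reps.mean())
    elif intensity is not None:
        mean_int = float(intensity)
    else:
        raise ValueError("provide intensity or replicate_intensities")
    conc = (mean_int - curve.intercept) / curve.slope
    in_range = curve.range_low_mg_ml <= conc <= curve.range_high_mg_ml
    return ConcentrationResult(concentration_mg_ml=conc, in_range=in_range,
                               mean_intensity=mean_int)


def normalize_to_standard(concentration_mg_ml: float, standard_mg_ml: float = 1.0) -> float:
    """Concentration as a dimensionless ratio to a reference standard."""
    if standard_mg_ml <= 0:
        raise ValueError("standard concentration must be > 0")
    return concentration_mg_ml / standard_mg_ml
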