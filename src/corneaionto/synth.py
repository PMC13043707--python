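"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of the study's data so
the whole pipeline is testable without instrument files:

- albumin emission spectra peaking at 345 nm with peak intensity linear
  in concentration over the 0.125–2 mg/ml detection range;
- a serially diluted calibration series {2, 1, 0.5, 0.25, 0.125} mg/ml;
- whole-cornea FTIR spectra as sums of Gaussian bands on a 400–4000 cm⁻¹
  grid (2 cm⁻¹ spacing) with a smooth baseline drift, using per-group
  presets whose band positions and second-derivative area fractions
  follow the reported group characteristics (e.g. control hydroxyl
  fractions strOH/syOH/asyOH = 31.1/2.2/4.7 % of total area);
- per-group concentration samples (n = 10) anchored at the reported group
  means (1.7 mg/ml at 6–7 mA, 2.7 mg/ml at 500 mA).

Every generator is a pure function of its arguments and seed: a fixed
seed reproduces the output bit for bit.

Because band fractions are reported on the rectified second derivative,
preset fractions are imposed on the analytic |d²| area of each Gaussian
band (|d²| area = 4 e^{-1/2} A/σ), i.e. band amplitudes are chosen as
A ∝ fraction × σ.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fluorescence import EMISSION_GRID_NM, EmissionSpectrum
from .ftir import BandDefinition, IRSpectrum
from .stats import GroupData

__all__ = [
    "FTIR_GRID_CM1",
    "GaussianBand",
    "gen_emission_spectrum",
    "gen_calibration_series",
    "gen_ftir_spectrum",
    "gen_group_concentrations",
    "gen_cornea_config",
    "load_ftir_presets",
    "analytic_band_profile",
    "analytic_band_area_abs_d2",
    "analytic_area_fractions",
    "DEFAULT_CONCENTRATION_DESIGN",
    "CALIBRATION_CONCENTRATIONS",
]

#: FTIR acquisition grid: 400–4000 cm⁻¹ at the 2 cm⁻¹ instrument resolution.
FTIR_GRID_CM1 = np.arange(400.0, 4001.0, 2.0)

#: Serial dilution used for the fluorescence calibration curve (mg/ml).
CALIBRATION_CONCENTRATIONS = (2.0, 1.0, 0.5, 0.25, 0.125)

#: Group mean albumin concentrations (mg/ml) in the receiver chamber,
#: n = 10 per group.  Currents <= 5 mA share a low mean (their pairwise
#: differences are not distinguishable); 6–7 mA plateau at 1.7 mg/ml and
#: the 500 mA damage model reaches 2.7 mg/ml.
DEFAULT_CONCENTRATION_DESIGN: Mapping[str, float] = {
    "0.5": 0.5, "1": 0.5, "2": 0.5, "3": 0.5, "4": 0.5, "5": 0.5,
    "6": 1.7, "7": 1.7, "500": 2.7,
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian component: centre (cm⁻¹), FWHM (cm⁻¹) and its target
    fraction (%) of the total rectified-second-derivative spectral area."""

    name: str
    center_cm1: float
    fwhm_cm1: float
    frac_pct: float

    @property
    def sigma(self) -> float:
        return self.fwhm_cm1 * _FWHM_TO_SIGMA


# ---------------------------------------------------------------------------
# fluorescence generators
# ---------------------------------------------------------------------------

def gen_emission_spectrum(
    concentration_mg_ml: float,
    seed: int | None = 0,
    slope: float = 1000.0,
    intercept: float = 0.0,
    peak_nm: float = 345.0,
    fwhm_nm: float = 60.0,
    noise_rel: float = 0.02,
    group: str = "",
    replicate_id: str = "",
) -> EmissionSpectrum:
    """Synthetic tryptophan emission scan on the 290–450 nm, 10 nm grid.

    The noiseless spectrum is a Gaussian centred at ``peak_nm`` whose peak
    intensity is ``slope * concentration + intercept``; noise is additive
    Gaussian with SD ``noise_rel`` relative to the local intensity.
    """
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    peak = slope * concentration_mg_ml + intercept
    clean = peak * np.exp(-0.5 * ((EMISSION_GRID_NM - peak_nm) / sigma) ** 2)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + noise_rel * rng.standard_normal(clean.size))
    return EmissionSpectrum(
        wavelengths_nm=EMISSION_GRID_NM.copy(),
        intensities=np.clip(clean, 0.0, None),
        group=group,
        replicate_id=replicate_id,
    )


def gen_calibration_series(
    seed: int | None = 0,
    concentrations: Sequence[float] = CALIBRATION_CONCENTRATIONS,
    slope: float = 1000.0,
    intercept: float = 20.0,
    noise_rel: float = 0.02,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Standards table (conc_mg_ml, intensity) for the serial dilution.

    Intensities are peak (345 nm) readings, linear in concentration, with
    relative Gaussian noise; ``n_replicates`` repeats the dilution series.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        for conc in concentrations:
            clean = slope * conc + intercept
            noisy = clean * (1.0 + noise_rel * rng.standard_normal()) if noise_rel > 0 else clean
            rows.append({"conc_mg_ml": conc, "intensity": noisy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FTIR generators
# ---------------------------------------------------------------------------

def load_ftir_presets(path=None) -> dict[str, tuple[GaussianBand, ...]]:
    """Per-group band presets (control, low_current, mid_current,
    high_current, extreme) from the shipped YAML preset file."""
    if path is None:
        text = (
            importlib.resources.files("corneaionto") / "data" / "ftir_presets.yaml"
        ).read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for preset, entries in raw["presets"].items():
        out[preset] = tuple(
            GaussianBand(
                name=e["name"],
                center_cm1=float(e["center_cm1"]),
                fwhm_cm1=float(e["fwhm_cm1"]),
                frac_pct=float(e["frac_pct"]),
            )
            for e in entries
        )
    return out


def _band_amplitudes(bands: Sequence[GaussianBand], amplitude_scale: float) -> np.ndarray:
    """Amplitudes imposing the preset |d²|-area fractions.

    |d²| area of a Gaussian is 4 e^{-1/2} A/σ, so fractions are set by
    A ∝ frac × σ; the common factor is fixed so the tallest noiseless
    band peaks at ``amplitude_scale`` absorbance units.
    """
    raw = np.array([b.frac_pct * b.sigma for b in bands])
    if raw.max() <= 0:
        raise ValueError("preset has no positive band fractions")
    return raw * (amplitude_scale / raw.max())


def _smooth_baseline(nu: np.ndarray) -> np.ndarray:
    """Gentle curved instrumental drift (offset + tilt + shallow curvature)."""
    x = (nu - nu[0]) / (nu[-1] - nu[0])
    return 0.08 + 0.05 * x + 0.06 * (x - 0.5) ** 2


def gen_ftir_spectrum(
    group: str,
    seed: int | None = 0,
    presets: Mapping[str, Sequence[GaussianBand]] | None = None,
    bands: Sequence[GaussianBand] | None = None,
    noise_sd: float = 0.002,
    amplitude_scale: float = 1.2,
    with_baseline: bool = True,
    replicate_id: str = "",
) -> IRSpectrum:
    """Synthetic whole-cornea absorbance spectrum for one group/replicate.

    Sum of Gaussian bands (explicit ``bands`` or the named group preset)
    plus a smooth baseline drift and additive Gaussian noise of SD
    ``noise_sd`` absorbance units.
    """
    if bands is None:
        presets = presets if presets is not None else load_ftir_presets()
        if group not in presets:
            raise KeyError(
                f"unknown preset {group!r}; available: {sorted(presets)}"
            )
        bands = presets[group]
    amps = _band_amplitudes(bands, amplitude_scale)
    nu = FTIR_GRID_CM1
    ab = np.zeros_like(nu)
    for band, amp in zip(bands, amps):
        ab += amp * np.exp(-0.5 * ((nu - band.center_cm1) / band.sigma) ** 2)
    if with_baseline:
        ab = ab + _smooth_baseline(nu)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ab = ab + noise_sd * rng.standard_normal(nu.size)
    return IRSpectrum(
        wavenumbers_cm1=nu.copy(), absorbance=ab, group=group,
        replicate_id=replicate_id, stage="raw",
    )


def analytic_band_profile(
    bands: Sequence[GaussianBand], amplitude_scale: float, nu: np.ndarray,
    deriv: int = 0,
) -> np.ndarray:
    """Noiseless, baseline-free band model (or its exact 2nd derivative)."""
    amps = _band_amplitudes(bands, amplitude_scale)
    out = np.zeros_like(nu, dtype=float)
    for band, amp in zip(bands, amps):
        z = (nu - band.center_cm1) / band.sigma
        g = amp * np.exp(-0.5 * z**2)
        if deriv == 0:
            out += g
        elif deriv == 2:
            out += g * (z**2 - 1.0) / band.sigma**2
        else:
            raise ValueError("deriv must be 0 or 2")
    return out


def analytic_band_area_abs_d2(
    bands: Sequence[GaussianBand],
    window: BandDefinition,
    amplitude_scale: float = 1.2,
    resolution_cm1: float = 0.05,
) -> float:
    """Exact |d²| area of the band model over one integration window
    (fine-grid quadrature of the analytic second derivative)."""
    nu = np.arange(window.lo_cm1, window.hi_cm1 + resolution_cm1, resolution_cm1)
    d2 = analytic_band_profile(bands, amplitude_scale, nu, deriv=2)
    return float(np.trapezoid(np.abs(d2), nu))


def analytic_area_fractions(
    bands: Sequence[GaussianBand],
    windows: Sequence[BandDefinition],
    amplitude_scale: float = 1.2,
) -> dict[str, float]:
    """Ground-truth area percentages (of full-spectrum |d²| area) for each
    integration window of the generator model."""
    full = BandDefinition("__full__", FTIR_GRID_CM1[0], FTIR_GRID_CM1[-1])
    total = analytic_band_area_abs_d2(bands, full, amplitude_scale, resolution_cm1=0.2)
    return {
        w.name: 100.0
        * analytic_band_area_abs_d2(bands, w, amplitude_scale, resolution_cm1=0.05)
        / total
        for w in windows
    }


# ---------------------------------------------------------------------------
# concentrations & configs
# ---------------------------------------------------------------------------

def gen_group_concentrations(
    seed: int | None = 0,
    design: Mapping[str, float] = DEFAULT_CONCENTRATION_DESIGN,
    sd_mg_ml: float = 0.1,
    n_per_group: int = 10,
) -> list[GroupData]:
    """Per-group concentration samples: seeded normals truncated at zero."""
    rng = np.random.default_rng(seed)
    groups = []
    for label, mean in design.items():
        vals = mean + sd_mg_ml * rng.standard_normal(n_per_group)
        groups.append(GroupData(label=str(label), values=np.clip(vals, 0.0, None)))
    return groups


def gen_cornea_config(overrides: Mapping | None = None) -> str:
    """YAML text of the cornea run configuration.

    With no overrides this is byte-identical to the shipped default
    config.  ``thermal_boundary`` and ``solver`` overrides merge key-wise;
    a ``layers`` override is a mapping of layer name to field overrides
    (e.g. ``{"layers": {"epithelium": {"sigma_S_per_m": 5e-4}}}``).
    Unknown keys raise.
    """
    from .config import packaged_config_text, DEFAULT_CONFIG_NAME

    text = packaged_config_text(DEFAULT_CONFIG_NAME)
    if not overrides:
        return text
    raw = yaml.safe_load(text)
    for key, val in overrides.items():
        if key not in raw:
            raise KeyError(f"unknown config key {key!r}")
        if key == "layers":
            if not isinstance(val, Mapping):
                raise TypeError("'layers' override must map layer name -> field overrides")
            by_name = {entry["name"]: entry for entry in raw["layers"]}
            for lname, fields in val.items():
                if lname not in by_name:
                    raise KeyError(f"unknown layer {lname!r}")
                unknown = set(fields) - set(by_name[lname])
                if unknown:
                    raise KeyError(f"unknown layer fields: {sorted(unknown)}")
                by_name[lname].update(fields)
        elif isinstance(raw[key], dict):
            if not isinstance(val, Mapping):
                raise TypeError(f"{key!r} override must be a mapping")
            unknown = set(val) - set(raw[key])
            if unknown:
                raise KeyError(f"unknown {key} keys: {sorted(unknown)}")
            raw[key] = {**raw[key], **val}
        else:
            raw[key] = val
    return yaml.safe_dump(raw, sort_keys=False)
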