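"""Thermal-safety classification of simulated corneal temperatures.

Four zones, ordered by temperature:

- ``thermoneutral``: within or below the healthy corneal baseline band
  (upper edge 36 °C) — both the ocular and the general tissue margin hold;
- ``physiological``: above the ocular baseline but below the 41 °C onset
  of reversible cellular stress;
- ``caution``: 41 °C <= T < 43 °C, reversible stress;
- ``damage``: T >= 43 °C, irreversible thermal injury.

Thresholds are right-closed upward: a temperature exactly at a threshold
enters the stricter zone (T = 43 °C classifies as damage).  All edges are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .bioheat import TemperatureField, layer_max_temperatures, surface_temperature

__all__ = [
    "ZONES",
    "SafetyThresholds",
    "SafetyReport",
    "classify_temperature",
    "classify_field",
    "safe_current_window",
]

#: Zone labels in increasing order of severity.
ZONES = ("thermoneutral", "physiological", "caution", "damage")


@dataclass(frozen=True)
class SafetyThresholds:
    ocular_low_C: float = 32.0
    ocular_high_C: float = 36.0
    caution_C: float = 41.0
    damage_C: float = 43.0

    def __post_init__(self) -> None:
        if not (self.ocular_low_C < self.ocular_high_C < self.caution_C < self.damage_C):
            raise ValueError("thresholds must satisfy ocular_low < ocular_high < caution < damage")


def classify_temperature(T_C: float, thresholds: SafetyThresholds | None = None) -> str:
    """Map a temperature to its safety zone label."""
    thresholds = thresholds or SafetyThresholds()
    if not math.isfinite(T_C):
        raise ValueError(f"non-finite temperature: {T_C!r}")
    if T_C >= thresholds.damage_C:
        return "damage"
    if T_C >= thresholds.caution_C:
        return "caution"
    if T_C > thresholds.ocular_high_C:
        return "physiological"
    return "thermoneutral"


@dataclass(frozen=True)
class SafetyReport:
    """Per (current, time, layer) zone labels plus a safe-window summary.

    ``table`` columns: current_mA, time_s, layer, T_max_C, zone.
    ``window`` maps (zone, time_s) -> largest current whose *surface*
    classification does not exceed that zone.
    """

    table: pd.DataFrame
    window: dict[tuple[str, float], float] = field(default_factory=dict)


def classify_field(
    field_: TemperatureField,
    thresholds: SafetyThresholds | None = None,
    current_mA: float | None = None,
) -> pd.DataFrame:
    """Zone labels from per-layer maxima of one solved field, long format."""
    thresholds = thresholds or SafetyThresholds()
    if field_.T_C.size == 0:
        raise ValueError("empty temperature field")
    rows = []
    for t in field_.times_s:
        maxima = layer_max_temperatures(field_, t)
        maxima["surface"] = surface_temperature(field_, t)
        for layer, tmax in maxima.items():
            rows.append(
                {
                    "current_mA": current_mA,
                    "time_s": t,
                    "layer": layer,
                    "T_max_C": tmax,
                    "zone": classify_temperature(tmax, thresholds),
                }
            )
    return pd.DataFrame(rows)


def classify_fields(
    fields: dict[float, TemperatureField],
    thresholds: SafetyThresholds | None = None,
) -> SafetyReport:
    """Classify a family of solved fields keyed by applied current (mA)."""
    thresholds = thresholds or SafetyThresholds()
    tables = [
        classify_field(fld, thresholds, current_mA=i_mA)
        for i_mA, fld in sorted(fields.items())
    ]
    table = pd.concat(tables, ignore_index=True)
    window = {}
    surf = table[table.layer == "surface"]
    for t in sorted(surf.time_s.unique()):
        at_t = surf[surf.time_s == t]
        for zone_idx, zone in enumerate(ZONES):
            ok = at_t[at_t.zone.map(ZONES.index) <= zone_idx]
            if len(ok):
                window[(zone, float(t))] = float(ok.current_mA.max())
    return SafetyReport(table=table, window=window)


def safe_current_window(report: SafetyReport, zone: str, time_s: float) -> float | None:
    """Largest current whose surface stays at or below ``zone`` at ``time_s``."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    return report.window.get((zone, float(time_s)))
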