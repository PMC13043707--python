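"""Configuration loading for the cornea stack, protocol, boundary and solver.

Two YAML configurations ship with the package:

``cornea_default.yaml``
    The four-layer rabbit cornea (tear film / epithelium / stroma /
    endothelium, 12/50/430/20 µm) with its published electrical
    conductivities, literature thermal properties for water-rich soft
    tissue, and a raw (scale = 1, unlimited-current) Joule source.

``reference_calibrated.yaml``
    The same geometry and conductivities with the calibrated thermal /
    boundary / source parameter set that reproduces the reference
    simulated temperature distribution (see docs/methods.md).  This is a
    single pinned parameter set used for every reported temperature.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .bioheat import SolverConfig, ThermalBoundary
from .electro import CorneaStack, CurrentProtocol, LayerSpec

__all__ = [
    "RunConfig",
    "default_stack",
    "default_layer_table",
    "load_config",
    "load_config_text",
    "load_packaged_config",
    "config_to_dict",
    "DEFAULT_CONFIG_NAME",
    "CALIBRATED_CONFIG_NAME",
]

DEFAULT_CONFIG_NAME = "cornea_default.yaml"
CALIBRATED_CONFIG_NAME = "reference_calibrated.yaml"

#: Geometry (µm) and electrical conductivity (S/m) of the four corneal
#: layers, anterior to posterior.
LAYER_TABLE = (
    ("tear_film", 12.0, 0.0, 12.0, 1.5),
    ("epithelium", 50.0, 12.0, 62.0, 0.0004),
    ("stroma", 430.0, 62.0, 492.0, 0.25),
    ("endothelium", 20.0, 492.0, 512.0, 0.0066),
)

#: Default disc area: radius 0.6 cm -> pi * 0.6**2 cm².
DEFAULT_AREA_CM2 = 1.1309733552923256

#: The nine protocol currents (mA); the last is the non-clinical damage model.
PROTOCOL_CURRENTS_MA = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 500.0)

_THERMAL_DEFAULTS = {
    "tear_film": dict(k_W_mK=0.60, rho_kg_m3=1000.0, c_J_kgK=4180.0),
    "epithelium": dict(k_W_mK=0.58, rho_kg_m3=1050.0, c_J_kgK=3800.0),
    "stroma": dict(k_W_mK=0.58, rho_kg_m3=1050.0, c_J_kgK=3800.0),
    "endothelium": dict(k_W_mK=0.58, rho_kg_m3=1050.0, c_J_kgK=3800.0),
}


@dataclass(frozen=True)
class RunConfig:
    """Bundle of everything a thermal run needs."""

    stack: CorneaStack
    protocol: CurrentProtocol
    boundary: ThermalBoundary
    solver: SolverConfig


def default_layer_table() -> tuple[tuple, ...]:
    return LAYER_TABLE


def default_stack(area_cm2: float = DEFAULT_AREA_CM2) -> CorneaStack:
    """The published four-layer stack with literature thermal properties."""
    layers = [
        LayerSpec(
            name=name,
            thickness_um=th,
            position_start_um=p0,
            position_end_um=p1,
            sigma_S_per_m=sigma,
            **_THERMAL_DEFAULTS[name],
        )
        for name, th, p0, p1, sigma in LAYER_TABLE
    ]
    return CorneaStack(layers, area_cm2=area_cm2)


_LAYER_KEYS = {
    "name",
    "thickness_um",
    "sigma_S_per_m",
    "k_W_mK",
    "rho_kg_m3",
    "c_J_kgK",
    "w_b_per_s",
    "q_met_W_m3",
}


def _parse(raw: Mapping[str, Any]) -> RunConfig:
    try:
        layer_dicts = raw["layers"]
        area = float(raw["area_cm2"])
    except KeyError as exc:
        raise KeyError(f"config missing required key: {exc}") from exc

    layers = []
    pos = 0.0
    for entry in layer_dicts:
        unknown = set(entry) - _LAYER_KEYS
        if unknown:
            raise KeyError(f"unknown layer keys: {sorted(unknown)}")
        th = float(entry["thickness_um"])
        layers.append(
            LayerSpec(
                name=entry["name"],
                thickness_um=th,
                position_start_um=pos,
                position_end_um=pos + th,
                sigma_S_per_m=float(entry["sigma_S_per_m"]),
                k_W_mK=float(entry.get("k_W_mK", 0.58)),
                rho_kg_m3=float(entry.get("rho_kg_m3", 1050.0)),
                c_J_kgK=float(entry.get("c_J_kgK", 3800.0)),
                w_b_per_s=float(entry.get("w_b_per_s", 0.0)),
                q_met_W_m3=float(entry.get("q_met_W_m3", 0.0)),
            )
        )
        pos += th
    stack = CorneaStack(layers, area_cm2=area)

    protocol = CurrentProtocol(
        current_mA=float(raw.get("current_mA", 0.5)),
        duration_s=float(raw.get("duration_s", 60.0)),
        report_times_s=tuple(raw.get("report_times_s", (10.0, 30.0, 60.0))),
    )

    tb = raw.get("thermal_boundary", {})
    boundary = ThermalBoundary(
        h_conv_W_m2K=float(tb.get("h_conv_W_m2K", 10.0)),
        e_evap_W_m2=float(tb.get("e_evap_W_m2", 0.0)),
        T_ambient_C=float(tb.get("T_ambient_C", 25.0)),
        T_body_C=float(tb.get("T_body_C", 37.0)),
        h_post_W_m2K=float(tb.get("h_post_W_m2K", 10.0)),
    )

    sv = raw.get("solver", {})
    cv = sv.get("compliance_voltage_V", None)
    solver = SolverConfig(
        dt_s=float(sv.get("dt_s", 0.1)),
        dx_um=float(sv.get("dx_um", 2.0)),
        t_end_s=float(sv.get("t_end_s", 60.0)),
        theta=float(sv.get("theta", 1.0)),
        T_baseline_C=float(sv.get("T_baseline_C", 34.0)),
        source_scale=float(sv.get("source_scale", 1.0)),
        compliance_voltage_V=None if cv is None else float(cv),
    )
    return RunConfig(stack=stack, protocol=protocol, boundary=boundary, solver=solver)


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return _parse(raw)


def load_config_text(text: str) -> RunConfig:
    """Parse a run configuration from YAML text."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a mapping")
    return _parse(raw)


def packaged_config_text(name: str = CALIBRATED_CONFIG_NAME) -> str:
    return (
        importlib.resources.files("corneaionto") / "data" / name
    ).read_text(encoding="utf-8")


def load_packaged_config(name: str = CALIBRATED_CONFIG_NAME) -> RunConfig:
    """Load one of the configurations shipped with the package."""
    raw = yaml.safe_load(packaged_config_text(name))
    return _parse(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Round-trippable plain-dict form of a RunConfig (YAML schema)."""
    return {
        "area_cm2": cfg.stack.area_cm2,
        "current_mA": cfg.protocol.current_mA,
        "duration_s": cfg.protocol.duration_s,
        "report_times_s": list(cfg.protocol.report_times_s),
        "layers": [
            {
                "name": lay.name,
                "thickness_um": lay.thickness_um,
                "sigma_S_per_m": lay.sigma_S_per_m,
                "k_W_mK": lay.k_W_mK,
                "rho_kg_m3": lay.rho_kg_m3,
                "c_J_kgK": lay.c_J_kgK,
                "w_b_per_s": lay.w_b_per_s,
                "q_met_W_m3": lay.q_met_W_m3,
            }
            for lay in cfg.stack.layers
        ],
        "thermal_boundary": {
            "h_conv_W_m2K": cfg.boundary.h_conv_W_m2K,
            "e_evap_W_m2": cfg.boundary.e_evap_W_m2,
            "T_ambient_C": cfg.boundary.T_ambient_C,
            "T_body_C": cfg.boundary.T_body_C,
            "h_post_W_m2K": cfg.boundary.h_post_W_m2K,
        },
        "solver": {
            "dt_s": cfg.solver.dt_s,
            "dx_um": cfg.solver.dx_um,
            "t_end_s": cfg.solver.t_end_s,
            "theta": cfg.solver.theta,
            "T_baseline_C": cfg.solver.T_baseline_C,
            "source_scale": cfg.solver.source_scale,
            "compliance_voltage_V": cfg.solver.compliance_voltage_V,
        },
    }
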