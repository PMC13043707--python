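"""Electrical quantities of the layered cornea under constant applied current.

The cornea is treated as a series stack of planar resistive layers (tear
film, epithelium, stroma, endothelium).  A constant current ``I`` through a
cross-section ``A`` gives a single current density ``J = I/A`` shared by all
layers; each layer of thickness ``L`` and conductivity ``sigma`` contributes
a resistance ``L/(sigma*A)``, an ohmic voltage drop ``I*R``, and a volumetric
Joule heat source ``J**2/sigma`` that feeds the bioheat solver.

All public interfaces accept the bench units used in iontophoresis work
(mA, cm², µm); computation is done in SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "LayerSpec",
    "CorneaStack",
    "CurrentProtocol",
    "InvalidGeometryError",
    "current_density",
    "layer_resistance",
    "voltage_drop",
    "joule_volumetric_source",
    "total_stack_resistance",
    "effective_current",
]

UM_TO_M = 1e-6
CM2_TO_M2 = 1e-4
MA_TO_A = 1e-3


class InvalidGeometryError(ValueError):
    """Raised for non-physical stack geometry (non-positive area, empty stack...)."""


@dataclass(frozen=True)
class LayerSpec:
    """One corneal layer: geometry plus electrical and thermal constants.

    Parameters
    ----------
    name : str
        Layer label (e.g. ``"epithelium"``).
    thickness_um : float
        Layer thickness in µm (> 0).
    position_start_um, position_end_um : float
        Depth of the anterior/posterior faces from the anterior tear
        surface, µm.  ``position_end - position_start`` must equal the
        thickness.
    sigma_S_per_m : float
        Electrical conductivity, S/m (> 0).
    k_W_mK : float
        Thermal conductivity, W/m/K.
    rho_kg_m3 : float
        Density, kg/m³.
    c_J_kgK : float
        Specific heat, J/kg/K.
    w_b_per_s : float
        Perfusion rate, 1/s (0 for ex vivo tissue).
    q_met_W_m3 : float
        Metabolic volumetric heat, W/m³.
    """

    name: str
    thickness_um: float
    position_start_um: float
    position_end_um: float
    sigma_S_per_m: float
    k_W_mK: float = 0.58
    rho_kg_m3: float = 1050.0
    c_J_kgK: float = 3800.0
    w_b_per_s: float = 0.0
    q_met_W_m3: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise InvalidGeometryError(f"{self.name}: thickness must be > 0")
        if abs((self.position_end_um - self.position_start_um) - self.thickness_um) > 1e-9:
            raise InvalidGeometryError(
                f"{self.name}: position_end - position_start != thickness"
            )
        if self.sigma_S_per_m <= 0:
            raise InvalidGeometryError(f"{self.name}: sigma must be > 0")
        if self.k_W_mK <= 0 or self.rho_kg_m3 <= 0 or self.c_J_kgK <= 0:
            raise InvalidGeometryError(f"{self.name}: k, rho, c must be > 0")
        if self.w_b_per_s < 0 or self.q_met_W_m3 < 0:
            raise InvalidGeometryError(f"{self.name}: w_b and q_met must be >= 0")

    @property
    def thickness_m(self) -> float:
        return self.thickness_um * UM_TO_M


@dataclass(frozen=True)
class CorneaStack:
    """Ordered anterior→posterior sequence of contiguous layers plus the
    cross-sectional area (cm²) through which current flows."""

    layers: tuple[LayerSpec, ...]
    area_cm2: float

    def __init__(self, layers: Sequence[LayerSpec], area_cm2: float) -> None:
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "area_cm2", float(area_cm2))
        if not self.layers:
            raise InvalidGeometryError("stack needs at least one layer")
        if self.area_cm2 <= 0:
            raise InvalidGeometryError("area must be > 0")
        if abs(self.layers[0].position_start_um) > 1e-9:
            raise InvalidGeometryError("first layer must start at depth 0")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if abs(prev.position_end_um - nxt.position_start_um) > 1e-9:
                raise InvalidGeometryError(
                    f"layers {prev.name!r} and {nxt.name!r} are not contiguous"
                )

    @property
    def area_m2(self) -> float:
        return self.area_cm2 * CM2_TO_M2

    @property
    def total_thickness_um(self) -> float:
        return self.layers[-1].position_end_um

    def layer(self, name: str) -> LayerSpec:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)


@dataclass(frozen=True)
class CurrentProtocol:
    """Applied constant-current protocol.

    ``report_times_s`` are the exposure times at which depth profiles are
    reported (default 10/30/60 s as in transcorneal iontophoresis studies).
    """

    current_mA: float
    duration_s: float = 60.0
    report_times_s: tuple[float, ...] = (10.0, 30.0, 60.0)

    def __post_init__(self) -> None:
        if self.current_mA < 0:
            raise ValueError("current must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        object.__setattr__(self, "report_times_s", tuple(float(t) for t in self.report_times_s))
        for t in self.report_times_s:
            if not (0.0 <= t <= self.duration_s):
                raise ValueError("report times must lie in [0, duration]")

    @property
    def current_A(self) -> float:
        return self.current_mA * MA_TO_A


def current_density(protocol: CurrentProtocol, stack: CorneaStack) -> float:
    """Current density J = I/A in mA/cm², identical for every layer in series."""
    if stack.area_cm2 <= 0:
        raise InvalidGeometryError("area must be > 0")
    return protocol.current_mA / stack.area_cm2


def layer_resistance(layer: LayerSpec, stack: CorneaStack) -> float:
    """Ohmic resistance of one layer, R = L/(sigma*A), in Ω."""
    if layer.sigma_S_per_m <= 0:
        raise ZeroDivisionError("layer conductivity must be > 0")
    return layer.thickness_m / (layer.sigma_S_per_m * stack.area_m2)


def total_stack_resistance(stack: CorneaStack) -> float:
    """Series resistance of the whole stack, Ω (epithelium-dominated)."""
    return sum(layer_resistance(lay, stack) for lay in stack.layers)


def voltage_drop(layer: LayerSpec, protocol: CurrentProtocol, stack: CorneaStack) -> float:
    """Ohm's-law voltage drop across one layer, V."""
    return protocol.current_A * layer_resistance(layer, stack)


def effective_current(
    protocol: CurrentProtocol,
    stack: CorneaStack,
    compliance_voltage_V: float | None = None,
) -> float:
    """Current actually delivered through the stack, in mA.

    A constant-current source can only sustain its setpoint while the
    required voltage ``I * R_total`` stays below its compliance voltage;
    beyond that the delivered current is voltage-limited to
    ``V_c / R_total``.  With ``compliance_voltage_V=None`` the setpoint is
    delivered unconditionally.
    """
    if compliance_voltage_V is None:
        return protocol.current_mA
    if compliance_voltage_V < 0:
        raise ValueError("compliance voltage must be >= 0")
    i_max_mA = compliance_voltage_V / total_stack_resistance(stack) / MA_TO_A
    return min(protocol.current_mA, i_max_mA)


def joule_volumetric_source(
    layer: LayerSpec,
    protocol: CurrentProtocol,
    stack: CorneaStack,
    scale: float = 1.0,
    compliance_voltage_V: float | None = None,
) -> float:
    """Volumetric Joule heat Q = scale * J²/sigma in W/m³ for one layer.

    ``scale`` is a dimensionless source calibration factor; ``scale=1``
    gives the raw ohmic dissipation density.  Within one protocol Q is
    constant in time and piecewise-constant in depth.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    i_eff_A = effective_current(protocol, stack, compliance_voltage_V) * MA_TO_A
    j_A_m2 = i_eff_A / stack.area_m2
    return scale * j_A_m2**2 / layer.sigma_S_per_m
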