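"""Device-sizing calculations for the bioreactor actuators.

Three small, closed-form calculations used to dimension the instrument:

* winding wire: length, resistance, drive voltage and ohmic power of a copper
  wire of a given AWG gauge under a mass budget, and gauge selection under a
  voltage ceiling (more turns per kilogram favours thin wire, supply voltage
  limits how thin);
* heater: conduction-only sizing ``P = m cp (Tf - Ti) / dt`` of the band
  resistor that must warm the batch in a prescribed time;
* stirrer: impeller Reynolds number ``Re = rho Ni Di^2 / mu`` (Ni in rev/s)
  and turbulent-regime power draw ``P = Np rho Ni^3 Di^5`` for a Rushton-type
  turbine of power number Np.

Physical constants are standard handbook values: copper resistivity
1.724e-8 ohm m at 20 degC, copper density 8960 kg/m^3, AWG diameters from the
ASTM B258 geometric series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import ConfigError

__all__ = [
    "COPPER_RESISTIVITY",
    "COPPER_DENSITY",
    "LB_TO_KG",
    "INSULATION_FACTOR",
    "WireGauge",
    "AWG_TABLE",
    "WireRequirements",
    "wire_requirements",
    "select_gauge",
    "HeaterSpec",
    "heater_power",
    "MixingSpec",
    "ReynoldsResult",
    "reynolds",
    "impeller_power",
]

COPPER_RESISTIVITY = 1.724e-8  # ohm m at 20 degC
COPPER_DENSITY = 8960.0  # kg/m^3
LB_TO_KG = 0.45359
# Effective (enamelled) diameter / bare diameter; 0.8128 mm bare 20 AWG ->
# 0.90 mm winding pitch.
INSULATION_FACTOR = 1.107

# Reynolds number above which a stirred tank is conventionally turbulent.
TURBULENT_RE = 1.0e4
LAMINAR_RE = 10.0


@dataclass(frozen=True)
class WireGauge:
    """Copper magnet wire of a given AWG size.

    ``bare_diameter`` (m), ``resistance_per_m`` (ohm/m at 20 degC) and
    ``linear_mass`` (kg/m) are mutually consistent through the circular
    cross-section: R' = rho_cu / A, m' = rho_density A.
    """

    awg: int
    bare_diameter: float
    resistance_per_m: float
    linear_mass: float

    @classmethod
    def from_awg(cls, awg: int) -> "WireGauge":
        """ASTM B258 geometric series: d = 0.127 mm * 92^((36 - awg) / 39)."""
        d = 0.000127 * 92.0 ** ((36.0 - awg) / 39.0)
        area = math.pi * d * d / 4.0
        return cls(
            awg=awg,
            bare_diameter=d,
            resistance_per_m=COPPER_RESISTIVITY / area,
            linear_mass=COPPER_DENSITY * area,
        )

    @property
    def insulated_diameter(self) -> float:
        """Effective winding pitch including the enamel build (m)."""
        return self.bare_diameter * INSULATION_FACTOR


AWG_TABLE: dict[int, WireGauge] = {awg: WireGauge.from_awg(awg) for awg in range(14, 31)}


class WireRequirements(NamedTuple):
    length: float  # m
    resistance: float  # ohm
    voltage: float  # V
    power: float  # W


def wire_requirements(gauge: WireGauge, wire_mass: float, current: float) -> WireRequirements:
    """Length, resistance, drive voltage and ohmic power for a wire-mass budget."""
    if not wire_mass > 0.0:
        raise ConfigError(f"wire_mass must be > 0, got {wire_mass}")
    if current < 0.0:
        raise ConfigError(f"current must be >= 0, got {current}")
    length = wire_mass / gauge.linear_mass
    resistance = length * gauge.resistance_per_m
    voltage = current * resistance
    return WireRequirements(length, resistance, voltage, current * voltage)


def select_gauge(
    candidates: Sequence[WireGauge], wire_mass: float, current: float, v_max: float
) -> WireGauge:
    """Thinnest gauge that still drives ``current`` under ``v_max``.

    Thinner wire gives more turns per kilogram, so among the feasible gauges
    (drive voltage <= v_max) the smallest bare diameter wins; ties break
    toward the larger AWG number.  Raises :class:`ConfigError` naming the
    closest candidate if none is feasible.
    """
    candidates = list(candidates)
    if not candidates:
        raise ConfigError("select_gauge needs at least one candidate gauge")
    reqs = {g.awg: wire_requirements(g, wire_mass, current) for g in candidates}
    feasible = [g for g in candidates if reqs[g.awg].voltage <= v_max]
    if not feasible:
        closest = min(candidates, key=lambda g: reqs[g.awg].voltage)
        raise ConfigError(
            f"no candidate gauge meets v_max = {v_max} V; closest is "
            f"{closest.awg} AWG needing {reqs[closest.awg].voltage:.2f} V"
        )
    return min(feasible, key=lambda g: (g.bare_diameter, -g.awg))


@dataclass(frozen=True)
class HeaterSpec:
    """Conduction-only heater sizing inputs (mass in g, cp in J/(g K))."""

    mass: float
    t_initial: float
    t_final: float
    heating_time: float
    cp: float = 4.1806  # liquid water, J/(g K)

    def __post_init__(self) -> None:
        if not self.heating_time > 0.0:
            raise ConfigError("HeaterSpec.heating_time must be > 0")
        if self.t_final < self.t_initial:
            raise ConfigError("HeaterSpec.t_final must be >= t_initial")
        if not (self.mass > 0.0 and self.cp > 0.0):
            raise ConfigError("HeaterSpec.mass and cp must be > 0")


def heater_power(spec: HeaterSpec) -> float:
    """Required heater power ``P = m cp (Tf - Ti) / dt`` in watts."""
    return spec.mass * spec.cp * (spec.t_final - spec.t_initial) / spec.heating_time


@dataclass(frozen=True)
class MixingSpec:
    """Impeller mixing inputs.

    ``speed`` is the rotational speed in rev/s; use :meth:`from_rpm` for RPM
    input.  ``power_number`` is the dimensionless impeller constant Np (about 5
    for a Rushton turbine in the turbulent regime).
    """

    fluid_density: float  # kg/m^3
    dynamic_viscosity: float  # Pa s
    impeller_diameter: float  # m
    speed: float  # rev/s
    power_number: float

    def __post_init__(self) -> None:
        for name in ("fluid_density", "dynamic_viscosity", "impeller_diameter", "power_number"):
            if not getattr(self, name) > 0.0:
                raise ConfigError(f"MixingSpec.{name} must be > 0")
        if self.speed < 0.0:
            raise ConfigError("MixingSpec.speed must be >= 0")

    @classmethod
    def from_rpm(
        cls,
        fluid_density: float,
        dynamic_viscosity: float,
        impeller_diameter: float,
        speed_rpm: float,
        power_number: float,
    ) -> "MixingSpec":
        return cls(
            fluid_density, dynamic_viscosity, impeller_diameter, speed_rpm / 60.0, power_number
        )


class ReynoldsResult(NamedTuple):
    value: float
    regime: str


def reynolds(spec: MixingSpec) -> ReynoldsResult:
    """Impeller Reynolds number ``rho Ni Di^2 / mu`` and its regime label."""
    re = spec.fluid_density * spec.speed * spec.impeller_diameter**2 / spec.dynamic_viscosity
    if re > TURBULENT_RE:
        regime = "turbulent"
    elif re < LAMINAR_RE:
        regime = "laminar"
    else:
        regime = "transitional"
    return ReynoldsResult(re, regime)


def impeller_power(spec: MixingSpec) -> float:
    """Stirring power ``P = Np rho Ni^3 Di^5`` in watts.

    The correlation holds in the turbulent regime where Np is constant; a
    warning (not an error) is emitted outside it.
    """
    re = reynolds(spec)
    if re.regime != "turbulent" and spec.speed > 0.0:
        warnings.warn(
            f"impeller_power outside the turbulent regime (Re = {re.value:.3g}, "
            f"{re.regime}); the constant-Np correlation may not hold",
            stacklevel=2,
        )
    return spec.power_number * spec.fluid_density * spec.speed**3 * spec.impeller_diameter**5
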