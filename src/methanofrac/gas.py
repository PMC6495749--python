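"""Headspace gas chemistry for sealed bottles and sparged chemostats.

Converts between fill conditions, incubation-temperature pressures, molar gas
amounts and aqueous concentrations.  Ideal-gas behaviour is assumed throughout
(all pressures here are <= 2.4 atm at >= 295 K).  Aqueous solubility uses a
Henry's-law constant with a van 't Hoff temperature correction; this is a
deliberate simplification of full aqueous speciation (no salinity/Setschenow
correction, no activity coefficients), so aqueous estimates carry roughly 10%
uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping

#: Gas constant in l*atm/(mol*K).
R_L_ATM = 0.082057

#: Room temperature used for bottle fills, K (22 degC).
ROOM_TEMPERATURE_K = 295.15

__all__ = [
    "R_L_ATM",
    "ROOM_TEMPERATURE_K",
    "BottleGeometry",
    "GasMixture",
    "HenryModel",
    "DEFAULT_HENRY",
    "isochoric_pressure",
    "headspace_amount",
    "pressure_from_amount",
    "aqueous_from_partial_pressure",
    "sparge_partial_pressure",
]


@dataclass(frozen=True)
class BottleGeometry:
    """Geometry and fill conditions of a sealed culture vessel."""

    liquid_volume_l: float
    headspace_volume_l: float
    fill_temperature_k: float = ROOM_TEMPERATURE_K
    fill_pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.liquid_volume_l <= 0 or self.headspace_volume_l <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.fill_temperature_k <= 0:
            raise ValueError("fill temperature must be positive (kelvin)")
        if self.fill_pressure_atm < 0:
            raise ValueError("fill pressure must be non-negative")


#: 245-ml serum bottle with 100 ml of medium.
SERUM_BOTTLE = BottleGeometry(liquid_volume_l=0.100, headspace_volume_l=0.145)

#: 2-liter gas-tight flask with 1.5 liters of medium.
CULTURE_FLASK = BottleGeometry(liquid_volume_l=1.5, headspace_volume_l=0.5)


@dataclass(frozen=True)
class GasMixture:
    """Gas composition as mole fractions (must sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.fractions.values()):
            raise ValueError("mole fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {total})")

    def partial_pressure(self, component: str, total_pressure_atm: float) -> float:
        """Partial pressure (atm) of one component at the given total pressure."""
        return self.fractions.get(component, 0.0) * total_pressure_atm


@dataclass(frozen=True)
class HenryModel:
    """Henry's-law solubility with van 't Hoff temperature dependence.

    c(p, T) = p * kh_ref * exp(vant_hoff_b * (1/T - 1/t_ref))  [mol/l]
    """

    kh_ref_mol_per_l_atm: float
    t_ref_k: float = 298.15
    vant_hoff_b_k: float = 0.0

    def __post_init__(self) -> None:
        if self.kh_ref_mol_per_l_atm <= 0:
            raise ValueError("Henry constant must be positive")
        if self.t_ref_k <= 0:
            raise ValueError("reference temperature must be positive (kelvin)")


#: Freshwater Henry constants at 298.15 K with van 't Hoff coefficients.
DEFAULT_HENRY: Dict[str, HenryModel] = {
    "H2": HenryModel(7.8e-4, 298.15, 500.0),
    "CH4": HenryModel(1.4e-3, 298.15, 1700.0),
    "CO2": HenryModel(3.4e-2, 298.15, 2400.0),
}


def isochoric_pressure(
    fill_pressure_atm: float,
    fill_temperature_k: float,
    incubation_temperature_k: float,
) -> float:
    """Pressure after heating a sealed, fixed-volume headspace: P2 = P1*T2/T1."""
    if fill_temperature_k <= 0 or incubation_temperature_k <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if fill_pressure_atm < 0:
        raise ValueError("pressure must be non-negative")
    return fill_pressure_atm * incubation_temperature_k / fill_temperature_k


def headspace_amount(
    partial_pressure_atm: float, headspace_volume_l: float, temperature_k: float
) -> float:
    """Moles of a gas in the headspace from its partial pressure: n = PV/RT."""
    if headspace_volume_l <= 0 or temperature_k <= 0:
        raise ValueError("volume and temperature must be positive")
    if partial_pressure_atm < 0:
        raise ValueError("partial pressure must be non-negative")
    return partial_pressure_atm * headspace_volume_l / (R_L_ATM * temperature_k)


def pressure_from_amount(n_mol: float, headspace_volume_l: float, temperature_k: float) -> float:
    """Partial pressure (atm) exerted by n moles in the headspace: P = nRT/V."""
    if headspace_volume_l <= 0 or temperature_k <= 0:
        raise ValueError("volume and temperature must be positive")
    if n_mol < 0:
        raise ValueError("amount must be non-negative")
    return n_mol * R_L_ATM * temperature_k / headspace_volume_l


def aqueous_from_partial_pressure(
    p_atm: float, model: HenryModel, temperature_k: float
) -> float:
    """Equilibrium aqueous concentration (micromolar) at partial pressure p.

    Linear in p; the van 't Hoff factor lowers solubility of sparingly soluble
    gases as temperature rises.
    """
    if p_atm < 0:
        raise ValueError("partial pressure must be non-negative")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    c_mol_per_l = (
        p_atm
        * model.kh_ref_mol_per_l_atm
        * math.exp(model.vant_hoff_b_k * (1.0 / temperature_k - 1.0 / model.t_ref_k))
    )
    return c_mol_per_l * 1e6


def sparge_partial_pressure(flows_ml_per_min: Mapping[str, float]) -> GasMixture:
    """Gas composition delivered by a mass-flow-blended sparge.

    Mole fraction of each component equals its flow over the total flow; in an
    open sparged reactor at ambient pressure the partial pressure of each
    component is its fraction times 1 atm.
    """
    if any(f < 0 for f in flows_ml_per_min.values()):
        raise ValueError("flows must be non-negative")
    total = sum(flows_ml_per_min.values())
    if total <= 0:
        raise ValueError("total flow must be positive")
    return GasMixture({k: v / total for k, v in flows_ml_per_min.items()})
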