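"""IPCC Tier 2 coefficients and emission factors, with provenance tracking.

A :class:`ParameterSet` carries every coefficient the per-period livestock
engine and the soil nitrogen pathways need. Each value must be accompanied by
a provenance string ("IPCC 2006 default", "paper", or "assumed"); loading a
YAML parameter block without provenance fails, so a run can always say where
its numbers came from.

Defaults follow the 2006 IPCC Guidelines for cattle (energy system of
Chapter 10), with the deep-bedding methane conversion factor set to 20% for a
12 °C mean annual temperature and a six-month midden storage assumption.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

import yaml

IPCC = "IPCC 2006 default"
PAPER = "paper"
ASSUMED = "assumed"

#: kg N2O per kg N2O-N (molecular weight ratio 44/28).
N2O_N_TO_N2O = 44.0 / 28.0

_DEFAULT_PROVENANCE: dict[str, str] = {
    "cfi_maintenance": IPCC,
    "ca_housing": IPCC,
    "ca_pasture": IPCC,
    "c_growth_steer": IPCC,
    "c_growth_heifer": IPCC,
    "mature_weight_steer": ASSUMED,
    "mature_weight_heifer": ASSUMED,
    "ym_pasture": ASSUMED,
    "ym_housing": ASSUMED,
    "energy_per_kg_ch4": IPCC,
    "ge_per_kg_dm": IPCC,
    "urinary_energy_frac": IPCC,
    "ash_frac": IPCC,
    "b0": IPCC,
    "ch4_density": IPCC,
    "mcf_deep_bedding": PAPER,
    "mcf_pasture": IPCC,
    "annual_temp": PAPER,
    "storage_months": PAPER,
    "n_retention_intercept": IPCC,
    "n_retention_slope": IPCC,
    "ef1_soil": IPCC,
    "ef3_deep_bedding": IPCC,
    "ef3_prp_cattle": IPCC,
    "ef3_prp_sheep": IPCC,
    "ef4_volatilisation": IPCC,
    "ef5_leaching": IPCC,
    "frac_gas_ms": IPCC,
    "frac_leach": IPCC,
}


@dataclass(frozen=True)
class ParameterSet:
    """Coefficients for the Tier 2 livestock engine and soil N2O pathways.

    Units: energies MJ, masses kg, emission factors kg N2O-N (or NH3-N,
    NO3-N) per kg N, MCF and Ym in percent.
    """

    # Net energy for maintenance: NEm = cfi * liveweight^0.75 (MJ/d).
    cfi_maintenance: float = 0.322
    # Activity coefficient Ca (fraction of NEm) by location.
    ca_housing: float = 0.0
    ca_pasture: float = 0.17
    # Growth-equation coefficient C by sex (castrates 1.0, females 0.8).
    c_growth_steer: float = 1.0
    c_growth_heifer: float = 0.8
    # Mature weights (kg); set to the finishing targets of the herd.
    mature_weight_steer: float = 620.0
    mature_weight_heifer: float = 555.0
    # Methane conversion factor Ym (% of gross energy) by location.
    ym_pasture: float = 6.5
    ym_housing: float = 6.5
    # Energy content of methane (MJ/kg) and of feed dry matter (MJ/kg DM).
    energy_per_kg_ch4: float = 55.65
    ge_per_kg_dm: float = 18.45
    # Volatile-solids excretion: urinary energy and ash fractions.
    urinary_energy_frac: float = 0.04
    ash_frac: float = 0.08
    # Manure CH4: maximum producing capacity (m3 CH4/kg VS) and density.
    b0: float = 0.18
    ch4_density: float = 0.67
    # Methane conversion factors of the manure system (%).
    mcf_deep_bedding: float = 20.0
    mcf_pasture: float = 1.0
    annual_temp: float = 12.0
    storage_months: int = 6
    # N retention: Nret(g/d) = ADG*(268 - 7.03*NEg/ADG), / 1000 / 6.25.
    n_retention_intercept: float = 268.0
    n_retention_slope: float = 7.03
    # Soil and manure N2O emission/partition factors (kg N per kg N).
    ef1_soil: float = 0.01
    ef3_deep_bedding: float = 0.01
    ef3_prp_cattle: float = 0.02
    ef3_prp_sheep: float = 0.01
    ef4_volatilisation: float = 0.01
    ef5_leaching: float = 0.0075
    frac_gas_ms: float = 0.30
    frac_leach: float = 0.30
    #: provenance string per field name; every field must have one.
    provenance: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PROVENANCE)
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        fractions = (
            "ca_housing", "ca_pasture", "urinary_energy_frac", "ash_frac",
            "ef1_soil", "ef3_deep_bedding", "ef3_prp_cattle", "ef3_prp_sheep",
            "ef4_volatilisation", "ef5_leaching", "frac_gas_ms", "frac_leach",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("ym_pasture", "ym_housing"):
            v = getattr(self, name)
            if not 0.0 < v < 15.0:
                raise ValueError(f"{name} must lie in (0, 15), got {v}")
        if abs(self.energy_per_kg_ch4 - 55.65) > 1e-9:
            raise ValueError("energy_per_kg_ch4 is the physical constant 55.65 MJ/kg")
        for name in (
            "cfi_maintenance", "c_growth_steer", "c_growth_heifer",
            "mature_weight_steer", "mature_weight_heifer", "b0",
            "ch4_density", "ge_per_kg_dm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (f.name for f in fields(self) if f.name != "provenance"):
            if name not in self.provenance:
                raise ValueError(f"parameter {name!r} lacks a provenance string")

    # -- convenience accessors ---------------------------------------------
    def ca(self, location: str) -> float:
        return self.ca_housing if location == "housing" else self.ca_pasture

    def ym(self, location: str) -> float:
        return self.ym_housing if location == "housing" else self.ym_pasture

    def mcf(self, location: str) -> float:
        return self.mcf_deep_bedding if location == "housing" else self.mcf_pasture

    def c_growth(self, sex: str) -> float:
        return self.c_growth_steer if sex == "steer" else self.c_growth_heifer

    def mature_weight(self, sex: str) -> float:
        return (
            self.mature_weight_steer if sex == "steer" else self.mature_weight_heifer
        )

    def replace(self, **changes: float) -> "ParameterSet":
        """Copy with some values changed; provenance of changed values is
        marked "assumed" unless given explicitly via ``provenance=``."""
        prov = dict(self.provenance)
        explicit = changes.pop("provenance", None)
        for k in changes:
            prov[k] = ASSUMED
        if explicit:
            prov.update(explicit)
        return dataclasses.replace(self, provenance=prov, **changes)

    # -- YAML IO ------------------------------------------------------------
    def to_yaml(self, path: str) -> None:
        block = {
            f.name: {"value": getattr(self, f.name),
                     "provenance": self.provenance[f.name]}
            for f in fields(self) if f.name != "provenance"
        }
        with open(path, "w") as fh:
            yaml.safe_dump({"tier2_parameters": block}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        block = doc.get("tier2_parameters", doc)
        values: dict[str, Any] = {}
        prov: dict[str, str] = {}
        for name, entry in block.items():
            if not isinstance(entry, Mapping) or "provenance" not in entry:
                raise ValueError(
                    f"parameter {name!r} must be a mapping with 'value' and "
                    f"'provenance' keys"
                )
            values[name] = entry["value"]
            prov[name] = str(entry["provenance"])
        return cls(provenance=prov, **values)
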