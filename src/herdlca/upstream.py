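"""Farmlet-level pool emissions: soil N2O, lime CO2 and embedded burdens.

These burdens are not attributable to any single animal at source: nitrogen
applied to fields (inorganic fertiliser, farmyard manure, crop residues of
reseeded leys, excreta deposited by the co-grazing ewe flock), lime
dissolution, and the upstream production and transport of every purchased
input. They enter the ledger at ``farmlet_pool`` scope and are later split
between the sheep and cattle enterprises and distributed across the herd.

Upstream (embedded) emission factors are user-supplied configuration: the
defaults shipped here are plausible literature-magnitude values flagged
"assumed" and should be replaced with database values for any real
assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .params import N2O_N_TO_N2O, ParameterSet
from .records import (
    AN_PRODUCTION,
    BARLEY_PRODUCTION,
    CO2,
    CROP_RESIDUES,
    EWES_ON_PASTURE,
    FERTILISER_APPLICATION,
    FYM_APPLICATION,
    LEACHING,
    N2O,
    OTHERS,
    SCOPE_POOL,
    SSP_PRODUCTION,
    EmissionRecord,
)

#: Admissible inventory keys (the material-input rows of a farmlet inventory).
INVENTORY_KEYS: tuple[str, ...] = (
    "fertiliser_n", "fertiliser_p", "fertiliser_k", "lime", "fym_t",
    "glyphosate", "fluroxypyr", "seed_grass", "seed_clover", "diesel_l",
    "soybean", "straw",
    "tkm_soybean_sea", "tkm_soybean_road", "tkm_straw_road",
    "tkm_fertiliser_road",
)

#: Upstream source label per inventory key; keys absent here pool to Others.
_UPSTREAM_LABELS: dict[str, str] = {
    "fertiliser_n": AN_PRODUCTION,
    "fertiliser_p": SSP_PRODUCTION,
    "straw": BARLEY_PRODUCTION,
}


class MissingFactorError(KeyError):
    """An inventory quantity has no resolvable emission factor."""


@dataclass(frozen=True)
class FarmletInventory:
    """Annual material inputs of one farmlet, plus the configured nitrogen
    depositions the pool pathways need (sheep excreta; crop-residue N of
    reseeded systems; FYM nitrogen content)."""

    farmlet_id: str
    area_ha: float
    quantities: Mapping[str, float] = field(default_factory=dict)
    sheep_excreta_n_kg: float = 0.0
    crop_residue_n_kg: float = 0.0
    fym_n_per_tonne: float = 6.0  # kg N/t fresh FYM; assumed

    def __post_init__(self) -> None:
        unknown = set(self.quantities) - set(INVENTORY_KEYS)
        if unknown:
            raise ValueError(f"unknown inventory keys: {sorted(unknown)}")
        bad = {k: v for k, v in self.quantities.items() if v < 0}
        if bad:
            raise ValueError(f"inventory quantities must be >= 0: {bad}")
        if min(self.sheep_excreta_n_kg, self.crop_residue_n_kg,
               self.fym_n_per_tonne, self.area_ha) < 0:
            raise ValueError("inventory scalars must be >= 0")

    def get(self, key: str) -> float:
        return float(self.quantities.get(key, 0.0))


@dataclass(frozen=True)
class UpstreamEFTable:
    """kg CO2-eq per inventory unit, with provenance per entry."""

    factors: Mapping[str, float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.factors.items() if v < 0}
        if bad:
            raise ValueError(f"emission factors must be >= 0: {bad}")

    def ef(self, key: str) -> float:
        try:
            return float(self.factors[key])
        except KeyError:
            raise MissingFactorError(key)

    def scaled(self, factor: float) -> "UpstreamEFTable":
        return UpstreamEFTable(
            {k: v * factor for k, v in self.factors.items()}, self.provenance
        )

    @classmethod
    def default(cls) -> "UpstreamEFTable":
        """Assumed, editable embedded factors (kg CO2-eq per unit)."""
        factors = {
            "fertiliser_n": 8.9,       # per kg N as ammonium nitrate
            "fertiliser_p": 1.8,       # per kg P as single superphosphate
            "fertiliser_k": 0.6,       # per kg K
            "lime": 0.55,              # per kg: production + carbonate CO2
            "fym_t": 0.0,              # on-farm manure: no embedded burden
            "glyphosate": 10.0,        # per kg active ingredient
            "fluroxypyr": 10.0,
            "seed_grass": 1.5,         # per kg seed
            "seed_clover": 1.5,
            "diesel_l": 3.2,           # per litre, incl. combustion
            "soybean": 0.7,            # per kg (no land-use change)
            "straw": 0.18,             # per kg barley-straw bedding
            "tkm_soybean_sea": 0.011,  # per tonne-km, ocean freight
            "tkm_soybean_road": 0.11,  # per tonne-km, lorry
            "tkm_straw_road": 0.11,
            "tkm_fertiliser_road": 0.11,
        }
        return cls(factors, {k: "assumed" for k in factors})


@dataclass(frozen=True)
class ReseedingSchedule:
    """Periodic pasture renewal: per-event inputs annualised over the
    sowing interval."""

    sowing_interval_years: float = 5.0
    per_event: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sowing_interval_years < 1:
            raise ValueError("sowing_interval_years must be >= 1")
        unknown = set(self.per_event) - set(INVENTORY_KEYS)
        if unknown:
            raise ValueError(f"unknown reseeding input keys: {sorted(unknown)}")


def soil_n2o(inv: FarmletInventory, params: ParameterSet) -> list[EmissionRecord]:
    """Direct and leaching-indirect soil N2O from every field N stream."""

    def rec(source: str, mass: float) -> EmissionRecord:
        return EmissionRecord(SCOPE_POOL, inv.farmlet_id, source, N2O, mass)

    fert_n = inv.get("fertiliser_n")
    fym_n = inv.get("fym_t") * inv.fym_n_per_tonne
    residue_n = inv.crop_residue_n_kg
    sheep_n = inv.sheep_excreta_n_kg

    out = [
        rec(FERTILISER_APPLICATION, fert_n * params.ef1_soil * N2O_N_TO_N2O),
        rec(FYM_APPLICATION, fym_n * params.ef1_soil * N2O_N_TO_N2O),
        rec(EWES_ON_PASTURE, sheep_n * params.ef3_prp_sheep * N2O_N_TO_N2O),
    ]
    if residue_n > 0:
        # Only reseeded systems incorporate residues; an unrenewed permanent
        # pasture contributes no residue record at all.
        out.append(rec(CROP_RESIDUES, residue_n * params.ef1_soil * N2O_N_TO_N2O))
    leach_n = (fert_n + fym_n + residue_n + sheep_n) * params.frac_leach
    out.append(rec(LEACHING, leach_n * params.ef5_leaching * N2O_N_TO_N2O))
    return out


def upstream_burdens(
    inv: FarmletInventory, efs: UpstreamEFTable
) -> list[EmissionRecord]:
    """Embedded CO2-eq of every purchased input and transport leg.

    Quantities multiply their factors; records take the dedicated production
    labels where one exists (ammonium nitrate, single superphosphate, barley
    straw) and pool under "Others" otherwise.
    """
    missing = [k for k in inv.quantities if k not in efs.factors]
    if missing:
        raise MissingFactorError(
            f"no upstream factor for inventory keys: {sorted(missing)}"
        )
    out = []
    for key, qty in inv.quantities.items():
        if qty == 0:
            continue
        label = _UPSTREAM_LABELS.get(key, OTHERS)
        out.append(
            EmissionRecord(SCOPE_POOL, inv.farmlet_id, label, CO2, qty * efs.ef(key))
        )
    return out


def reseeding_burdens(
    schedule: ReseedingSchedule, inv: FarmletInventory, efs: UpstreamEFTable
) -> list[EmissionRecord]:
    """Annualised share of periodic pasture-renewal operations.

    Each renewal's inputs are divided by the sowing interval; a system with
    no renewal events (permanent pasture) receives nothing.
    """
    out = []
    for key, qty in schedule.per_event.items():
        annual = qty / schedule.sowing_interval_years
        if annual == 0:
            continue
        out.append(
            EmissionRecord(SCOPE_POOL, inv.farmlet_id, OTHERS, CO2,
                           annual * efs.ef(key))
        )
    return out


def pool_emissions(
    inv: FarmletInventory,
    params: ParameterSet,
    efs: UpstreamEFTable | None = None,
    reseeding: ReseedingSchedule | None = None,
) -> list[EmissionRecord]:
    """Full farmlet-pool ledger: soil N2O + upstream + annualised reseeding."""
    efs = efs or UpstreamEFTable.default()
    out = soil_n2o(inv, params) + upstream_burdens(inv, efs)
    if reseeding is not None:
        out += reseeding_burdens(reseeding, inv, efs)
    return out
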