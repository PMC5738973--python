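"""Emission ledger records and the registry of recognised emission sources.

Every gram of greenhouse gas the package accounts for is carried as an
:class:`EmissionRecord` — a single (source, gas, mass) entry attributed either
to one animal or to a whole-farmlet pool. The set of admissible source labels
is closed: it mirrors the fourteen contribution lines a pasture-based beef
finishing system reports (rumen methane, manure-management pathways, soil
nitrous-oxide streams, embedded burdens of purchased inputs, and a pooled
"Others" line), so that every downstream aggregation can rely on a fixed
schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

CH4 = "CH4"
N2O = "N2O"
CO2 = "CO2"

SCOPE_ANIMAL = "animal"
SCOPE_POOL = "farmlet_pool"

# Source labels (the reporting rows of a system contribution table).
ENTERIC_CH4 = "Enteric fermentation (CH4)"
MANURE_CH4 = "Manure management (CH4)"
MANURE_N2O_DIRECT = "Manure management (direct N2O)"
MANURE_N2O_INDIRECT = "Manure management (indirect volatilisation N2O)"
BARLEY_PRODUCTION = "Barley production"
AN_PRODUCTION = "Ammonium nitrate production"
FERTILISER_APPLICATION = "Fertiliser application (N2O)"
EWES_ON_PASTURE = "Urine and dung from ewes on pasture (N2O)"
FYM_APPLICATION = "Farmyard manure application (N2O)"
CROP_RESIDUES = "Crop residues (N2O)"
LEACHING = "Indirect emissions from leaching (N2O)"
CATTLE_ON_PASTURE = "Urine and dung from cattle on pasture (N2O)"
SSP_PRODUCTION = "Single superphosphate production"
OTHERS = "Others"

#: Canonical reporting order of the fourteen source rows.
SOURCE_ORDER: tuple[str, ...] = (
    ENTERIC_CH4,
    MANURE_CH4,
    MANURE_N2O_DIRECT,
    MANURE_N2O_INDIRECT,
    BARLEY_PRODUCTION,
    AN_PRODUCTION,
    FERTILISER_APPLICATION,
    EWES_ON_PASTURE,
    FYM_APPLICATION,
    CROP_RESIDUES,
    LEACHING,
    CATTLE_ON_PASTURE,
    SSP_PRODUCTION,
    OTHERS,
)

# Admissible (gas, scopes) per source. Upstream production burdens are carried
# as CO2 mass already expressed in CO2-equivalent (characterization factor 1),
# the convention used when embedded factors arrive as single CO2-eq numbers.
SOURCE_REGISTRY: dict[str, dict] = {
    ENTERIC_CH4: {"gases": {CH4}, "scopes": {SCOPE_ANIMAL}},
    MANURE_CH4: {"gases": {CH4}, "scopes": {SCOPE_ANIMAL}},
    MANURE_N2O_DIRECT: {"gases": {N2O}, "scopes": {SCOPE_ANIMAL}},
    MANURE_N2O_INDIRECT: {"gases": {N2O}, "scopes": {SCOPE_ANIMAL}},
    BARLEY_PRODUCTION: {"gases": {CO2}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    AN_PRODUCTION: {"gases": {CO2}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    FERTILISER_APPLICATION: {"gases": {N2O}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    EWES_ON_PASTURE: {"gases": {N2O}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    FYM_APPLICATION: {"gases": {N2O}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    CROP_RESIDUES: {"gases": {N2O}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    # Leaching has both an animal-scope leg (grazed excreta) and a pool leg
    # (applied and ewe-deposited N).
    LEACHING: {"gases": {N2O}, "scopes": {SCOPE_ANIMAL, SCOPE_POOL}},
    CATTLE_ON_PASTURE: {"gases": {N2O}, "scopes": {SCOPE_ANIMAL}},
    SSP_PRODUCTION: {"gases": {CO2}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
    OTHERS: {"gases": {CO2}, "scopes": {SCOPE_POOL, SCOPE_ANIMAL}},
}

#: Sources attributed to individual animals by the per-period engine.
ANIMAL_SOURCES = frozenset({
    ENTERIC_CH4, MANURE_CH4, MANURE_N2O_DIRECT, MANURE_N2O_INDIRECT,
    CATTLE_ON_PASTURE, LEACHING,
})

#: Animal-scope sources that arise from excreta deposited on the shared
#: pasture (these carry a sheep-enterprise share during allocation; rumen and
#: housed-manure processes do not).
PASTURE_MANURE_SOURCES = frozenset({CATTLE_ON_PASTURE, LEACHING})


class UnknownSourceError(KeyError):
    """Raised for a source label outside the registry."""


@dataclass(frozen=True)
class EmissionRecord:
    """One ledger entry: a mass of one gas from one source, owned by one
    animal or one farmlet pool over an (optional) date interval."""

    scope: str
    owner_id: str
    source: str
    gas: str
    mass_kg: float
    period_start: Optional[date] = None
    period_end: Optional[date] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCE_REGISTRY:
            raise UnknownSourceError(
                f"unknown emission source label: {self.source!r}"
            )
        entry = SOURCE_REGISTRY[self.source]
        if self.gas not in entry["gases"]:
            raise ValueError(
                f"gas {self.gas!r} not admissible for source {self.source!r}"
            )
        if self.scope not in entry["scopes"]:
            raise ValueError(
                f"scope {self.scope!r} not admissible for source {self.source!r}"
            )
        if not math.isfinite(self.mass_kg) or self.mass_kg < 0:
            raise ValueError(
                f"mass_kg must be finite and >= 0, got {self.mass_kg!r} "
                f"({self.source}, {self.owner_id})"
            )

    def scaled(self, factor: float) -> "EmissionRecord":
        """Return a copy with mass multiplied by ``factor`` (>= 0)."""
        return EmissionRecord(
            self.scope, self.owner_id, self.source, self.gas,
            self.mass_kg * factor, self.period_start, self.period_end,
        )


def total_mass(records: Iterable[EmissionRecord], gas: str | None = None) -> float:
    """Sum ledger masses, optionally restricted to one gas."""
    return sum(r.mass_kg for r in records if gas is None or r.gas == gas)
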