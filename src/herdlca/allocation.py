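"""Enterprise allocation, GWP characterization and emissions intensity.

Pasture-origin burdens are shared between the cattle and sheep enterprises
that co-graze the platform, split by the economic value (or dry-matter
intake, for mass allocation) of the products each sends across the system
boundary. The cattle share of the pool is spread evenly across the herd;
emissions from each animal's own body processes stay individual, except that
burdens its excreta places on the shared pasture carry the same sheep
deduction as the pool. The design guarantees that summing every animal's
allocated total plus the sheep share recovers the system total exactly.

Characterization converts gas masses to CO2-equivalents with 100-year GWP
factor sets (28/265 for CH4/N2O, or the superseded 25/298 pair), and
emissions intensity divides by each animal's liveweight gain — the
functional unit of a finishing-stage assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import (
    CH4,
    CO2,
    N2O,
    PASTURE_MANURE_SOURCES,
    SCOPE_ANIMAL,
    SCOPE_POOL,
    EmissionRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AllocationBasis:
    """Enterprise allocation rule: product values (economic) or estimated
    dry-matter intakes (mass) for cattle and sheep."""

    method: str  # {"economic", "mass"}
    cattle_value: float
    sheep_value: float

    def __post_init__(self) -> None:
        if self.method not in ("economic", "mass"):
            raise ValueError("method must be 'economic' or 'mass'")
        if self.cattle_value <= 0 or self.sheep_value <= 0:
            raise ValueError("enterprise values must be > 0")


def enterprise_shares(basis: AllocationBasis) -> tuple[float, float]:
    """(cattle_share, sheep_share), summing to one."""
    total = basis.cattle_value + basis.sheep_value
    cattle = basis.cattle_value / total
    return cattle, 1.0 - cattle


@dataclass(frozen=True)
class GWPFactorSet:
    """100-year global warming potentials per gas."""

    name: str
    ch4: float
    n2o: float
    co2: float = 1.0

    def __post_init__(self) -> None:
        if self.co2 != 1.0:
            raise ValueError("co2 factor is 1 by definition")
        if self.ch4 <= 0 or self.n2o <= 0:
            raise ValueError("factors must be > 0")

    def factor(self, gas: str) -> float:
        try:
            return {CH4: self.ch4, N2O: self.n2o, CO2: self.co2}[gas]
        except KeyError:
            raise ValueError(f"unknown gas {gas!r}")


AR5_GWP100 = GWPFactorSet("AR5_GWP100", ch4=28.0, n2o=265.0)
AR4_GWP100 = GWPFactorSet("AR4_GWP100", ch4=25.0, n2o=298.0)
GWP_SETS = {"ar5": AR5_GWP100, "ar4": AR4_GWP100}


def characterize(
    records: Iterable[EmissionRecord], factors: GWPFactorSet
) -> tuple[float, dict[str, float]]:
    """Total kg CO2-eq and the per-source breakdown of a ledger."""
    breakdown: dict[str, float] = {}
    for r in records:
        breakdown[r.source] = breakdown.get(r.source, 0.0) + (
            r.mass_kg * factors.factor(r.gas)
        )
    return sum(breakdown.values()), breakdown


@dataclass
class EIResult:
    """Per-animal emissions intensity with its source breakdown."""

    animal_id: str
    lwg_kg: float
    total_co2e_kg: float
    ei: float
    breakdown: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lwg_kg <= 0:
            raise ValueError("EI is undefined for lwg <= 0")
        total = sum(self.breakdown.values()) if self.breakdown else self.total_co2e_kg
        if abs(total - self.total_co2e_kg) > 1e-9 * max(1.0, abs(self.total_co2e_kg)):
            raise ValueError("breakdown does not sum to total")
        if abs(self.ei * self.lwg_kg - self.total_co2e_kg) > 1e-9 * max(
            1.0, abs(self.total_co2e_kg)
        ):
            raise ValueError("ei * lwg must equal total")


def emissions_intensity(total_co2e: float, lwg: float) -> float:
    """kg CO2-eq per kg liveweight gain."""
    if lwg <= 0:
        raise ValueError(
            "emissions intensity undefined for non-growing animal (lwg <= 0)"
        )
    return total_co2e / lwg


def distribute_to_animals(
    pool: Sequence[EmissionRecord],
    animal_records: Mapping[str, Sequence[EmissionRecord]],
    cattle_share: float,
    n_animals: int | None = None,
) -> tuple[dict[str, list[EmissionRecord]], list[EmissionRecord]]:
    """Allocate the pool and the sheep deductions across the herd.

    Pool records are multiplied by the cattle share and split evenly
    (1/n each). Animal-scope records stay with their animal, except that
    pasture-deposition sources (excreta the sheep pasture also benefits from)
    are likewise multiplied by the cattle share.

    Returns the per-animal ledgers and the sheep-enterprise deduction as its
    own record list, so the grand total is conserved gas by gas.
    """
    if n_animals is None:
        n_animals = len(animal_records)
    if n_animals < 1:
        raise ValueError("need at least one animal")
    if not 0.0 <= cattle_share <= 1.0:
        raise ValueError("cattle_share must lie in [0, 1]")

    per_animal: dict[str, list[EmissionRecord]] = {}
    sheep: list[EmissionRecord] = []
    sheep_share = 1.0 - cattle_share
    for animal_id, records in animal_records.items():
        mine = []
        for r in records:
            if r.source in PASTURE_MANURE_SOURCES:
                mine.append(r.scaled(cattle_share))
                if sheep_share > 0:
                    sheep.append(r.scaled(sheep_share))
            else:
                mine.append(r)
        per_animal[animal_id] = mine

    for r in pool:
        if r.scope != SCOPE_POOL:
            raise ValueError(f"pool ledger contains non-pool record {r.source!r}")
        if sheep_share > 0:
            sheep.append(r.scaled(sheep_share))
        share_each = r.mass_kg * cattle_share / n_animals
        for animal_id in per_animal:
            per_animal[animal_id].append(
                EmissionRecord(
                    SCOPE_ANIMAL, animal_id, r.source, r.gas,
                    share_each, r.period_start, r.period_end,
                )
            )
    return per_animal, sheep


def ei_results(
    per_animal: Mapping[str, Sequence[EmissionRecord]],
    lwg_by_animal: Mapping[str, float],
    factors: GWPFactorSet,
) -> tuple[list[EIResult], list[str]]:
    """Characterize each animal's ledger and compute its EI.

    Animals with non-positive liveweight gain have undefined EI; they are
    excluded from the distribution (and reported) while their emissions still
    count in system totals upstream of this call.
    """
    results = []
    excluded = []
    for animal_id, records in per_animal.items():
        lwg = lwg_by_animal[animal_id]
        total, breakdown = characterize(records, factors)
        if lwg <= 0:
            excluded.append(animal_id)
            continue
        results.append(
            EIResult(animal_id, lwg, total, emissions_intensity(total, lwg),
                     breakdown)
        )
    if excluded:
        logger.warning(
            "%d non-finishing animal(s) excluded from EI distribution: %s",
            len(excluded), excluded,
        )
    return results, excluded
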