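"""Per-animal, per-period IPCC Tier 2 livestock emissions engine.

Emissions are computed for each animal for each period between two
consecutive weighings, with parameters switching by the animal's location
(pasture vs housing) and by the feed quality in force during the period:

* gross energy intake (GE, MJ/d) from the net-energy chain
  ``GE = [(NEm + NEa)/REM + NEg/REG] / (DE/100)``;
* enteric methane ``CH4 = GE * days * (Ym/100) / 55.65``;
* manure methane from volatile-solids excretion with a location-dependent
  methane conversion factor (deep bedding when housed, pasture deposition
  when grazing);
* nitrogen excretion (intake minus Tier 2 retention) feeding the
  manure-management direct and volatilisation-indirect N2O pathways when
  housed, and the pasture-deposition and leaching pathways when grazing.

Weight-loss periods are handled by flooring the growth energy and nitrogen
retention at zero: an animal that fails to gain still eats, ferments and
excretes, which is precisely why its emissions intensity diverges as its
daily gain approaches zero.

All period formulas accept numpy arrays, so whole trajectories evaluate in
one vectorised call; the named scalar operations are thin wrappers over the
same expressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np

from .feed import PASTURE, SILAGE, FeedQualitySeries
from .params import N2O_N_TO_N2O, ParameterSet
from .records import (
    CATTLE_ON_PASTURE,
    CH4,
    ENTERIC_CH4,
    LEACHING,
    MANURE_CH4,
    MANURE_N2O_DIRECT,
    MANURE_N2O_INDIRECT,
    N2O,
    SCOPE_ANIMAL,
    EmissionRecord,
)

SEXES = ("steer", "heifer")
LOCATIONS = ("pasture", "housing")


class EngineError(ValueError):
    """A Tier 2 computation received inputs outside its domain."""


@dataclass(frozen=True)
class WeighingEvent:
    date: date
    weight_kg: float
    location: str = "pasture"

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight_kg}")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")


@dataclass(frozen=True)
class AnimalRecord:
    """One growing animal: identity plus its dated liveweight trajectory."""

    animal_id: str
    farmlet_id: str
    sex: str
    events: tuple[WeighingEvent, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if len(self.events) < 2:
            raise ValueError(f"animal {self.animal_id}: needs >= 2 weighings")
        dates = [e.date for e in self.events]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"animal {self.animal_id}: weighing dates must strictly increase"
            )

    @property
    def entry_weight(self) -> float:
        return self.events[0].weight_kg

    @property
    def exit_weight(self) -> float:
        return self.events[-1].weight_kg

    @property
    def lwg(self) -> float:
        """Total liveweight gain on the platform (kg)."""
        return self.exit_weight - self.entry_weight

    @property
    def days_on_platform(self) -> int:
        return (self.events[-1].date - self.events[0].date).days

    @property
    def adg(self) -> float:
        """Whole-record average daily gain (kg/d)."""
        return self.lwg / self.days_on_platform


@dataclass(frozen=True)
class AnimalPeriod:
    """One half-open interval [start, end) between consecutive weighings,
    with the feed quality in force."""

    start: date
    end: date
    start_weight: float
    end_weight: float
    location: str
    de_pct: float
    cp_pct: float

    @property
    def days(self) -> int:
        return (self.end - self.start).days

    @property
    def mean_weight(self) -> float:
        return 0.5 * (self.start_weight + self.end_weight)

    @property
    def period_adg(self) -> float:
        return (self.end_weight - self.start_weight) / self.days


def periods_from_record(
    animal: AnimalRecord, feed: FeedQualitySeries
) -> list[AnimalPeriod]:
    """Cut an animal's record into periods and attach feed quality.

    The location of the period's first weighing decides both the parameter
    switches and the feed consumed: silage while housed, grazed pasture
    otherwise.
    """
    periods = []
    for a, b in zip(animal.events[:-1], animal.events[1:]):
        if b.date == a.date:
            raise EngineError(
                f"animal {animal.animal_id}: duplicate weighing date {a.date}"
            )
        feed_type = SILAGE if a.location == "housing" else PASTURE
        de, cp = feed.quality_at(animal.farmlet_id, feed_type, a.date, b.date)
        periods.append(
            AnimalPeriod(
                start=a.date, end=b.date,
                start_weight=a.weight_kg, end_weight=b.weight_kg,
                location=a.location, de_pct=de, cp_pct=cp,
            )
        )
    return periods


# ---------------------------------------------------------------------------
# Vectorised period formulas (accept scalars or aligned numpy arrays).
# ---------------------------------------------------------------------------

def rem(de_pct):
    """Ratio of net energy available for maintenance to digestible energy."""
    de = np.asarray(de_pct, dtype=float)
    return 1.123 - 4.092e-3 * de + 1.126e-5 * de**2 - 25.4 / de


def reg(de_pct):
    """Ratio of net energy available for growth to digestible energy."""
    de = np.asarray(de_pct, dtype=float)
    return 1.164 - 5.160e-3 * de + 1.308e-5 * de**2 - 37.4 / de


def _net_energies(mean_weight, adg, is_housed, c_sex, mature_w, p: ParameterSet):
    """NEm, NEa, NEg (MJ/d); growth energy floored at zero for weight loss."""
    w = np.asarray(mean_weight, dtype=float)
    gain = np.maximum(np.asarray(adg, dtype=float), 0.0)
    nem = p.cfi_maintenance * w**0.75
    ca = np.where(np.asarray(is_housed, bool), p.ca_housing, p.ca_pasture)
    nea = ca * nem
    ratio = w / (np.asarray(c_sex, dtype=float) * np.asarray(mature_w, dtype=float))
    neg = 22.02 * ratio**0.75 * gain**1.097
    return nem, nea, neg


def period_flows(
    days, mean_weight, adg, de_pct, cp_pct, is_housed, c_sex, mature_w,
    p: ParameterSet,
) -> dict[str, np.ndarray]:
    """Evaluate every Tier 2 pathway for aligned period arrays.

    Returns per-period masses (kg of each gas) keyed by source label, plus
    the intermediate ``ge`` (MJ/d) and ``n_ex`` (kg N) diagnostics.
    """
    de = np.asarray(de_pct, dtype=float)
    if np.any(de <= 0) or np.any(de >= 100):
        raise EngineError("DE must lie strictly between 0 and 100%")
    days = np.asarray(days, dtype=float)
    housed = np.asarray(is_housed, bool)

    nem, nea, neg = _net_energies(mean_weight, adg, housed, c_sex, mature_w, p)
    ge = ((nem + nea) / rem(de) + neg / reg(de)) / (de / 100.0)

    ym = np.where(housed, p.ym_housing, p.ym_pasture)
    ch4_enteric = ge * days * (ym / 100.0) / p.energy_per_kg_ch4

    vs_per_day = (
        (ge * (1.0 - de / 100.0) + p.urinary_energy_frac * ge)
        * (1.0 - p.ash_frac) / p.ge_per_kg_dm
    )
    mcf = np.where(housed, p.mcf_deep_bedding, p.mcf_pasture)
    ch4_manure = vs_per_day * days * p.b0 * p.ch4_density * (mcf / 100.0)

    cp = np.asarray(cp_pct, dtype=float)
    n_intake = (ge / p.ge_per_kg_dm) * (cp / 100.0) / 6.25
    gain = np.maximum(np.asarray(adg, dtype=float), 0.0)
    neg_per_gain = np.divide(
        neg, gain, out=np.zeros_like(np.asarray(neg, dtype=float)),
        where=gain > 0,
    )
    n_ret = np.where(
        gain > 0,
        gain * (p.n_retention_intercept - p.n_retention_slope * neg_per_gain)
        / 1000.0 / 6.25,
        0.0,
    )
    n_ret = np.maximum(n_ret, 0.0)
    n_ex = np.maximum(n_intake - n_ret, 0.0) * days

    housed_n = np.where(housed, n_ex, 0.0)
    grazed_n = np.where(~housed, n_ex, 0.0)
    n2o_direct = housed_n * p.ef3_deep_bedding * N2O_N_TO_N2O
    n2o_indirect = housed_n * p.frac_gas_ms * p.ef4_volatilisation * N2O_N_TO_N2O
    n2o_prp = grazed_n * p.ef3_prp_cattle * N2O_N_TO_N2O
    n2o_leach = grazed_n * p.frac_leach * p.ef5_leaching * N2O_N_TO_N2O

    return {
        "ge": ge,
        "n_ex": n_ex,
        ENTERIC_CH4: ch4_enteric,
        MANURE_CH4: ch4_manure,
        MANURE_N2O_DIRECT: n2o_direct,
        MANURE_N2O_INDIRECT: n2o_indirect,
        CATTLE_ON_PASTURE: n2o_prp,
        LEACHING: n2o_leach,
    }


# ---------------------------------------------------------------------------
# Named scalar operations.
# ---------------------------------------------------------------------------

def gross_energy_intake(
    period: AnimalPeriod, params: ParameterSet, sex: str
) -> float:
    """Gross energy intake (MJ/d) for one animal-period."""
    if not 0.0 < period.de_pct < 100.0:
        raise EngineError(f"DE {period.de_pct}% outside (0, 100)")
    nem, nea, neg = _net_energies(
        period.mean_weight, period.period_adg, period.location == "housing",
        params.c_growth(sex), params.mature_weight(sex), params,
    )
    ge = ((nem + nea) / rem(period.de_pct) + neg / reg(period.de_pct)) / (
        period.de_pct / 100.0
    )
    return float(ge)


def enteric_ch4(ge: float, ym: float, days: int) -> float:
    """Enteric methane (kg) from gross energy intake over ``days``."""
    if ge < 0 or days < 1:
        raise ValueError("ge must be >= 0 and days >= 1")
    return ge * days * (ym / 100.0) / 55.65


def manure_ch4(
    ge: float, de_pct: float, days: int, params: ParameterSet, location: str
) -> float:
    """Manure-management methane (kg) via volatile-solids excretion."""
    if ge < 0 or days < 1:
        raise ValueError("ge must be >= 0 and days >= 1")
    vs_per_day = (
        (ge * (1.0 - de_pct / 100.0) + params.urinary_energy_frac * ge)
        * (1.0 - params.ash_frac) / params.ge_per_kg_dm
    )
    return (
        vs_per_day * days * params.b0 * params.ch4_density
        * params.mcf(location) / 100.0
    )


def n_excretion(
    ge: float, cp_pct: float, period: AnimalPeriod, params: ParameterSet,
    sex: str,
) -> float:
    """Nitrogen excreted (kg N) over one period: intake minus retention,
    with retention floored at zero for non-gaining periods."""
    if cp_pct < 0:
        raise ValueError("cp_pct must be >= 0")
    n_intake = (ge / params.ge_per_kg_dm) * (cp_pct / 100.0) / 6.25
    gain = period.period_adg
    if gain > 0:
        _, _, neg = _net_energies(
            period.mean_weight, gain, period.location == "housing",
            params.c_growth(sex), params.mature_weight(sex), params,
        )
        n_ret = gain * (
            params.n_retention_intercept
            - params.n_retention_slope * float(neg) / gain
        ) / 1000.0 / 6.25
        n_ret = max(n_ret, 0.0)
    else:
        n_ret = 0.0
    return max(n_intake - n_ret, 0.0) * period.days


def manure_n2o(
    n_ex: float, location: str, params: ParameterSet,
    owner_id: str = "animal", period: tuple[date, date] | None = None,
) -> list[EmissionRecord]:
    """Nitrous-oxide records from one period's excreted N.

    Housed N feeds the manure-management direct and volatilisation-indirect
    pathways; grazed N feeds the pasture-deposition and leaching pathways.
    """
    if n_ex < 0:
        raise ValueError("n_ex must be >= 0")
    start, end = period if period is not None else (None, None)

    def rec(source: str, mass: float) -> EmissionRecord:
        return EmissionRecord(SCOPE_ANIMAL, owner_id, source, N2O, mass, start, end)

    if location == "housing":
        return [
            rec(MANURE_N2O_DIRECT, n_ex * params.ef3_deep_bedding * N2O_N_TO_N2O),
            rec(
                MANURE_N2O_INDIRECT,
                n_ex * params.frac_gas_ms * params.ef4_volatilisation * N2O_N_TO_N2O,
            ),
        ]
    return [
        rec(CATTLE_ON_PASTURE, n_ex * params.ef3_prp_cattle * N2O_N_TO_N2O),
        rec(
            LEACHING,
            n_ex * params.frac_leach * params.ef5_leaching * N2O_N_TO_N2O,
        ),
    ]


# ---------------------------------------------------------------------------
# Whole-animal evaluation.
# ---------------------------------------------------------------------------

_GASES = {
    ENTERIC_CH4: CH4,
    MANURE_CH4: CH4,
    MANURE_N2O_DIRECT: N2O,
    MANURE_N2O_INDIRECT: N2O,
    CATTLE_ON_PASTURE: N2O,
    LEACHING: N2O,
}


def periods_to_arrays(periods: Sequence[AnimalPeriod]) -> dict[str, np.ndarray]:
    """Pack a period list into aligned arrays for vectorised evaluation."""
    return {
        "days": np.array([p.days for p in periods], dtype=float),
        "mean_weight": np.array([p.mean_weight for p in periods]),
        "adg": np.array([p.period_adg for p in periods]),
        "de_pct": np.array([p.de_pct for p in periods]),
        "cp_pct": np.array([p.cp_pct for p in periods]),
        "is_housed": np.array([p.location == "housing" for p in periods]),
    }


def animal_emissions(
    animal: AnimalRecord,
    feed: FeedQualitySeries,
    params: ParameterSet,
    periods: Sequence[AnimalPeriod] | None = None,
) -> list[EmissionRecord]:
    """All livestock-origin emission records for one animal.

    ``periods`` may be supplied to skip the feed lookup (e.g. when the same
    trajectory is re-evaluated under perturbed parameters).
    """
    if periods is None:
        periods = periods_from_record(animal, feed)
    arrays = periods_to_arrays(periods)
    try:
        flows = period_flows(
            **arrays,
            c_sex=params.c_growth(animal.sex),
            mature_w=params.mature_weight(animal.sex),
            p=params,
        )
    except EngineError as exc:
        raise EngineError(f"animal {animal.animal_id}: {exc}") from exc

    out: list[EmissionRecord] = []
    for source, gas in _GASES.items():
        masses = flows[source]
        for p, m in zip(periods, masses):
            if m > 0.0:
                out.append(
                    EmissionRecord(
                        SCOPE_ANIMAL, animal.animal_id, source, gas,
                        float(m), p.start, p.end,
                    )
                )
    return out
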