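"""Model/Results interface over the per-animal emissions pipeline.

:class:`HerdLCAModel` is built from data — weighing records per farmlet, a
feed-quality series, farmlet inventories — plus configuration (Tier 2
parameters, upstream factors, allocation basis, GWP set). Its :meth:`fit`
runs inventory analysis, allocation and characterization, returning a
:class:`HerdLCAResults` that carries per-animal emissions intensities, the
per-source system breakdown, the representative-animal comparison, Monte
Carlo uncertainty, interpretation statistics and a ``summary()`` table.

    >>> model = HerdLCAModel.from_synthetic(seed=1)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import compare as cmp
from .allocation import (
    AR4_GWP100,
    AR5_GWP100,
    GWP_SETS,
    AllocationBasis,
    EIResult,
    GWPFactorSet,
    characterize,
    distribute_to_animals,
    ei_results,
    emissions_intensity,
    enterprise_shares,
)
from .feed import PASTURE, SILAGE, FeedQualitySeries
from .params import ParameterSet
from .records import (
    CATTLE_ON_PASTURE,
    ENTERIC_CH4,
    LEACHING,
    MANURE_CH4,
    MANURE_N2O_DIRECT,
    MANURE_N2O_INDIRECT,
    SOURCE_ORDER,
    EmissionRecord,
    total_mass,
)
from .tier2 import (
    AnimalPeriod,
    AnimalRecord,
    animal_emissions,
    period_flows,
    periods_from_record,
    periods_to_arrays,
)
from .upstream import (
    FarmletInventory,
    ReseedingSchedule,
    UpstreamEFTable,
    pool_emissions,
)

#: Enterprise product values behind the default allocation bases. Only the
#: resulting shares matter; these reproduce the platform's reported cattle
#: shares of 78% (economic) and 72% (dry-matter-intake mass basis).
ECONOMIC_BASIS = AllocationBasis("economic", cattle_value=78.0, sheep_value=22.0)
MASS_BASIS = AllocationBasis("mass", cattle_value=72.0, sheep_value=28.0)


def _resolve_gwp(gwp: GWPFactorSet | str) -> GWPFactorSet:
    if isinstance(gwp, GWPFactorSet):
        return gwp
    try:
        return GWP_SETS[gwp.lower()]
    except KeyError:
        raise ValueError(f"unknown GWP set {gwp!r}; expected 'ar5' or 'ar4'")


@dataclass
class _SystemCache:
    """Precomputed per-system trajectory arrays for fast re-evaluation."""

    herd: list[AnimalRecord]
    inventory: FarmletInventory
    reseeding: Optional[ReseedingSchedule]
    periods: dict[str, list[AnimalPeriod]]
    animal_ids: list[str]
    lwg: np.ndarray
    animal_idx: np.ndarray          # period -> animal position
    arrays: dict[str, np.ndarray]   # aligned period arrays
    sex_is_steer: np.ndarray        # per period


def _build_cache(
    herd: Sequence[AnimalRecord],
    feed: FeedQualitySeries,
    inventory: FarmletInventory,
    reseeding: Optional[ReseedingSchedule],
) -> _SystemCache:
    periods = {a.animal_id: periods_from_record(a, feed) for a in herd}
    ids = [a.animal_id for a in herd]
    idx, steer = [], []
    flat: list[AnimalPeriod] = []
    for k, a in enumerate(herd):
        for p in periods[a.animal_id]:
            flat.append(p)
            idx.append(k)
            steer.append(a.sex == "steer")
    return _SystemCache(
        herd=list(herd),
        inventory=inventory,
        reseeding=reseeding,
        periods=periods,
        animal_ids=ids,
        lwg=np.array([a.lwg for a in herd], dtype=float),
        animal_idx=np.array(idx, dtype=int),
        arrays=periods_to_arrays(flat),
        sex_is_steer=np.array(steer, dtype=bool),
    )


class HerdLCAModel:
    """Life-cycle emissions-intensity model of pasture-finished cattle.

    Parameters
    ----------
    herds : mapping of system label to animal weighing records
    feed : dated DE/CP series covering every system and feed type
    inventories : per-system annual material inputs
    params : Tier 2 coefficient set (defaults to the shipped set)
    upstream_efs : embedded emission factors (defaults flagged "assumed")
    reseeding : optional per-system pasture-renewal schedules
    allocation : enterprise allocation basis (default economic)
    gwp : characterization factor set, "ar5" (28/265) or "ar4" (25/298)
    """

    def __init__(
        self,
        herds: Mapping[str, Sequence[AnimalRecord]],
        feed: FeedQualitySeries,
        inventories: Mapping[str, FarmletInventory],
        params: ParameterSet | None = None,
        upstream_efs: UpstreamEFTable | None = None,
        reseeding: Mapping[str, ReseedingSchedule] | None = None,
        allocation: AllocationBasis | None = None,
        gwp: GWPFactorSet | str = "ar5",
    ):
        if set(herds) - set(inventories):
            raise ValueError("every herd needs a matching inventory")
        self.systems = sorted(herds)
        self.feed = feed
        self.params = params or ParameterSet()
        self.upstream_efs = upstream_efs or UpstreamEFTable.default()
        self.allocation = allocation or ECONOMIC_BASIS
        self.gwp = _resolve_gwp(gwp)
        reseeding = reseeding or {}
        self._cache = {
            s: _build_cache(herds[s], feed, inventories[s], reseeding.get(s))
            for s in self.systems
        }

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_synthetic(
        cls,
        seed: int = 0,
        systems: Sequence[str] = ("PP", "WC", "HS"),
        n_animals: int = 30,
        **kwargs,
    ) -> "HerdLCAModel":
        """Model over synthetic herds with the trial's per-system statistics."""
        from .synthetic import (
            generate_herd,
            study_feed_series,
            study_herd_spec,
            study_inventory,
            study_reseeding,
        )

        ss = np.random.SeedSequence(seed)
        state = ss.generate_state(len(systems) + 1)
        herds = {
            s: generate_herd(
                study_herd_spec(s, seed=int(state[k] % 2**31),
                                n_animals=n_animals)
            )
            for k, s in enumerate(systems)
        }
        feed = study_feed_series(systems, seed=int(state[-1] % 2**31))
        inventories = {s: study_inventory(s) for s in systems}
        reseeding = {
            s: r for s in systems if (r := study_reseeding(s)) is not None
        }
        return cls(herds, feed, inventories, reseeding=reseeding, **kwargs)

    @classmethod
    def from_csv(
        cls, herd_csv, feed_csv, inventories: Mapping[str, FarmletInventory],
        **kwargs,
    ) -> "HerdLCAModel":
        from .synthetic import herd_from_csv

        animals = herd_from_csv(herd_csv)
        herds: dict[str, list[AnimalRecord]] = {}
        for a in animals:
            herds.setdefault(a.farmlet_id, []).append(a)
        return cls(herds, FeedQualitySeries.from_csv(feed_csv), inventories,
                   **kwargs)

    # -- fast evaluation ----------------------------------------------------
    def _system_totals(
        self,
        cache: _SystemCache,
        params: ParameterSet,
        gwp: GWPFactorSet,
        cattle_share: float,
        de_offset: float = 0.0,
        cp_offset: float = 0.0,
        upstream_scale: float = 1.0,
    ) -> np.ndarray:
        """Per-animal allocated CO2-eq totals (animal order of the cache)."""
        arr = cache.arrays
        de = np.clip(arr["de_pct"] + de_offset, 0.5, 99.5)
        cp = np.clip(arr["cp_pct"] + cp_offset, 0.0, 99.5)
        c_sex = np.where(cache.sex_is_steer, params.c_growth_steer,
                         params.c_growth_heifer)
        mat_w = np.where(cache.sex_is_steer, params.mature_weight_steer,
                         params.mature_weight_heifer)
        flows = period_flows(
            arr["days"], arr["mean_weight"], arr["adg"], de, cp,
            arr["is_housed"], c_sex, mat_w, params,
        )
        n = len(cache.animal_ids)
        ch4 = np.bincount(
            cache.animal_idx, flows[ENTERIC_CH4] + flows[MANURE_CH4],
            minlength=n,
        )
        n2o_own = np.bincount(
            cache.animal_idx,
            flows[MANURE_N2O_DIRECT] + flows[MANURE_N2O_INDIRECT],
            minlength=n,
        )
        n2o_pasture = np.bincount(
            cache.animal_idx, flows[CATTLE_ON_PASTURE] + flows[LEACHING],
            minlength=n,
        )
        pool = pool_emissions(
            cache.inventory, params, self.upstream_efs.scaled(upstream_scale),
            cache.reseeding,
        )
        pool_co2e, _ = characterize(pool, gwp)
        return (
            ch4 * gwp.ch4
            + n2o_own * gwp.n2o
            + n2o_pasture * gwp.n2o * cattle_share
            + pool_co2e * cattle_share / n
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        gwp: GWPFactorSet | str | None = None,
        allocation: AllocationBasis | None = None,
    ) -> "HerdLCAResults":
        """Run inventory analysis, allocation and characterization."""
        gwp = _resolve_gwp(gwp) if gwp is not None else self.gwp
        allocation = allocation or self.allocation
        cattle_share, _ = enterprise_shares(allocation)

        per_system: dict[str, dict] = {}
        for s in self.systems:
            cache = self._cache[s]
            animal_ledgers = {
                a.animal_id: animal_emissions(
                    a, self.feed, self.params,
                    periods=cache.periods[a.animal_id],
                )
                for a in cache.herd
            }
            pool = pool_emissions(
                cache.inventory, self.params, self.upstream_efs, cache.reseeding
            )
            pre_total, _ = characterize(
                [r for recs in animal_ledgers.values() for r in recs] + pool, gwp
            )
            allocated, sheep = distribute_to_animals(
                pool, animal_ledgers, cattle_share, len(cache.herd)
            )
            lwg = {a.animal_id: a.lwg for a in cache.herd}
            results, excluded = ei_results(allocated, lwg, gwp)
            cattle_total = sum(
                characterize(recs, gwp)[0] for recs in allocated.values()
            )
            sheep_total, _ = characterize(sheep, gwp)
            per_system[s] = {
                "ledgers": allocated,
                "pool": pool,
                "sheep": sheep,
                "results": results,
                "excluded": excluded,
                "cattle_total_co2e": cattle_total,
                "sheep_total_co2e": sheep_total,
                "system_total_co2e": pre_total,
            }
        return HerdLCAResults(self, gwp, allocation, cattle_share, per_system)


class HerdLCAResults:
    """Fitted per-animal emissions intensities and their interpretation."""

    def __init__(
        self,
        model: HerdLCAModel,
        gwp: GWPFactorSet,
        allocation: AllocationBasis,
        cattle_share: float,
        per_system: dict[str, dict],
    ):
        self.model = model
        self.gwp = gwp
        self.allocation = allocation
        self.cattle_share = cattle_share
        self._sys = per_system
        self.animals = self._build_frame()

    # -- tabular views ------------------------------------------------------
    def _build_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.model.systems:
            cache = self.model._cache[s]
            by_id = {a.animal_id: a for a in cache.herd}
            for r in self._sys[s]["results"]:
                a = by_id[r.animal_id]
                row = {
                    "system": s,
                    "animal_id": r.animal_id,
                    "sex": a.sex,
                    "entry_weight": a.entry_weight,
                    "exit_weight": a.exit_weight,
                    "lwg": r.lwg_kg,
                    "days": a.days_on_platform,
                    "adg": a.adg,
                    "total_co2e": r.total_co2e_kg,
                    "ei": r.ei,
                }
                for source in SOURCE_ORDER:
                    row[source] = r.breakdown.get(source, 0.0)
                rows.append(row)
        return pd.DataFrame(rows)

    def results_for(self, system: str) -> list[EIResult]:
        return self._sys[system]["results"]

    def conservation_error(self, system: str) -> float:
        """Relative gap between Sigma per-animal + sheep share and the
        system total (should be ~1e-16; asserted <= 1e-9 in the suite)."""
        d = self._sys[system]
        total = d["system_total_co2e"]
        return abs(d["cattle_total_co2e"] + d["sheep_total_co2e"] - total) / total

    def system_breakdown(self) -> pd.DataFrame:
        """Per-source mean (min-max) emissions intensity per system, in the
        fourteen-source contribution-table layout plus a Total row."""
        rows = []
        for source in SOURCE_ORDER:
            row: dict = {"source": source}
            for s in self.model.systems:
                grp = self.animals[self.animals["system"] == s]
                per_kg = grp[source] / grp["lwg"]
                if per_kg.abs().max() == 0:
                    row[f"{s}_mean"] = np.nan
                    row[f"{s}_min"] = np.nan
                    row[f"{s}_max"] = np.nan
                else:
                    row[f"{s}_mean"] = per_kg.mean()
                    row[f"{s}_min"] = per_kg.min()
                    row[f"{s}_max"] = per_kg.max()
            rows.append(row)
        total_row: dict = {"source": "Total"}
        for s in self.model.systems:
            grp = self.animals[self.animals["system"] == s]
            total_row[f"{s}_mean"] = grp["ei"].mean()
            total_row[f"{s}_min"] = grp["ei"].min()
            total_row[f"{s}_max"] = grp["ei"].max()
        rows.append(total_row)
        return pd.DataFrame(rows)

    # -- representative-animal comparison -----------------------------------
    def _representative_ei(self, system: str) -> float:
        cache = self.model._cache[system]
        summary = cmp.HerdSummary.from_herd(cache.herd)
        entry_date = cache.herd[0].events[0].date
        rep = cmp.representative_animal(summary, entry_date=entry_date)

        # Yearly-mean feed quality, held constant.
        feed = self.model.feed
        de_p, cp_p = feed.yearly_mean(system, PASTURE)
        de_s, cp_s = feed.yearly_mean(system, SILAGE)
        frame = pd.DataFrame(
            [
                (system, PASTURE, date(2000, 1, 1), de_p, cp_p),
                (system, SILAGE, date(2000, 1, 1), de_s, cp_s),
            ],
            columns=list(FeedQualitySeries.COLUMNS),
        )
        rep_cache = _build_cache(
            [rep], FeedQualitySeries(frame), cache.inventory, cache.reseeding
        )
        # The pool is still shared by the full herd of n animals.
        n = len(cache.animal_ids)
        arr = rep_cache.arrays
        params, gwp = self.model.params, self.gwp
        c_sex = np.where(rep_cache.sex_is_steer, params.c_growth_steer,
                         params.c_growth_heifer)
        mat_w = np.where(rep_cache.sex_is_steer, params.mature_weight_steer,
                         params.mature_weight_heifer)
        flows = period_flows(
            arr["days"], arr["mean_weight"], arr["adg"], arr["de_pct"],
            arr["cp_pct"], arr["is_housed"], c_sex, mat_w, params,
        )
        ch4 = float(np.sum(flows[ENTERIC_CH4] + flows[MANURE_CH4]))
        n2o_own = float(
            np.sum(flows[MANURE_N2O_DIRECT] + flows[MANURE_N2O_INDIRECT])
        )
        n2o_pasture = float(np.sum(flows[CATTLE_ON_PASTURE] + flows[LEACHING]))
        pool = pool_emissions(
            cache.inventory, params, self.model.upstream_efs, cache.reseeding
        )
        pool_co2e, _ = characterize(pool, gwp)
        total = (
            ch4 * gwp.ch4 + n2o_own * gwp.n2o
            + n2o_pasture * gwp.n2o * self.cattle_share
            + pool_co2e * self.cattle_share / n
        )
        return emissions_intensity(total, rep.lwg)

    def representative(self) -> dict[str, dict]:
        """Per-system representative EI, mean individual EI and the
        aggregation bias (mean individual minus representative)."""
        out = {}
        for s in self.model.systems:
            eis = [r.ei for r in self._sys[s]["results"]]
            rep = self._representative_ei(s)
            out[s] = {
                "mean_individual_ei": float(np.mean(eis)),
                "representative_ei": rep,
                "bias": cmp.aggregation_bias(eis, rep),
            }
        return out

    # -- Monte Carlo --------------------------------------------------------
    def monte_carlo(self, spec: cmp.MCSpec, target: str = "mean") -> cmp.MCResult:
        """Propagate parameter distributions to per-system EI.

        ``target``: "mean" (herd-mean individual EI), "best" or "worst" (the
        animal so ranked in the deterministic fit). Distribution names are
        Tier 2 parameter fields plus "feed_de_offset", "feed_cp_offset" and
        "upstream_scale".
        """
        param_fields = {
            f for f in ParameterSet.__dataclass_fields__ if f != "provenance"
        }
        special = {"feed_de_offset", "feed_cp_offset", "upstream_scale"}
        unknown = set(spec.distributions) - param_fields - special
        if unknown:
            raise ValueError(f"unknown Monte Carlo parameters: {sorted(unknown)}")

        rank_idx: dict[str, int] = {}
        if target in ("best", "worst"):
            for s in self.model.systems:
                cache = self.model._cache[s]
                eis = {r.animal_id: r.ei for r in self._sys[s]["results"]}
                pick = (min if target == "best" else max)(eis, key=eis.get)
                rank_idx[s] = cache.animal_ids.index(pick)
        elif target != "mean":
            raise ValueError("target must be 'mean', 'best' or 'worst'")

        def model_fn(overrides: Mapping[str, float]) -> dict[str, float]:
            de_off = overrides.get("feed_de_offset", 0.0)
            cp_off = overrides.get("feed_cp_offset", 0.0)
            scale = max(overrides.get("upstream_scale", 1.0), 0.0)
            changes = {
                k: v for k, v in overrides.items() if k in param_fields
            }
            params = (
                self.model.params.replace(**changes)
                if changes else self.model.params
            )
            out = {}
            for s in self.model.systems:
                cache = self.model._cache[s]
                totals = self.model._system_totals(
                    cache, params, self.gwp, self.cattle_share,
                    de_off, cp_off, scale,
                )
                if target == "mean":
                    ok = cache.lwg > 0
                    out[s] = float(np.mean(totals[ok] / cache.lwg[ok]))
                else:
                    i = rank_idx[s]
                    out[s] = float(totals[i] / cache.lwg[i])
            return out

        return cmp.monte_carlo(model_fn, spec)

    # -- interpretation ------------------------------------------------------
    def interpret(self, equal_var: bool = False) -> cmp.ComparisonReport:
        return cmp.interpret(self.animals, equal_var=equal_var)

    def summary(self) -> str:
        """Human-readable per-system summary table."""
        lines = [
            "Emissions intensity of liveweight gain "
            f"(kg CO2-eq/kg LWG; GWP: {self.gwp.name}; "
            f"allocation: {self.allocation.method}, "
            f"cattle share {self.cattle_share:.2f})",
            "",
        ]
        rep = self.representative()
        rows = []
        for s in self.model.systems:
            grp = self.animals[self.animals["system"] == s]
            rows.append(
                {
                    "system": s,
                    "n": len(grp),
                    "mean EI": grp["ei"].mean(),
                    "min EI": grp["ei"].min(),
                    "max EI": grp["ei"].max(),
                    "mean ADG": grp["adg"].mean(),
                    "representative EI": rep[s]["representative_ei"],
                    "bias": rep[s]["bias"],
                }
            )
        table = pd.DataFrame(rows).to_string(index=False, float_format="%.2f")
        lines.append(table)
        excluded = {s: self._sys[s]["excluded"] for s in self.model.systems
                    if self._sys[s]["excluded"]}
        if excluded:
            lines.append("")
            lines.append(f"Animals excluded from EI distribution (lwg <= 0): "
                         f"{excluded}")
        return "\n".join(lines)
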