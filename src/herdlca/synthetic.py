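"""Synthetic herds, feed-quality series, inventories and packaged tables.

No individual-animal weighing records are publicly deposited for the study
system, so this module generates herds with the same statistical structure:
three farmlets of 30 Charolais x Hereford-Friesian calves entering at
weaning in autumn, housed October-April on silage, grazed otherwise, weighed
every two to four weeks, and sold at the first weighing at or above the sex
target (ca. 555 kg heifers, 620 kg steers).

Each animal's growth follows a three-phase piecewise-linear mean curve —
a post-weaning dip, a mid-season peak around 1.4-1.6 kg/d, and a finishing
slowdown — scaled by an animal-level average-daily-gain draw and perturbed
by period-level weighing noise. The curve is normalised per animal over its
expected time-to-target and the between-animal draw is shrunk by the
expected weighing-noise variance, so the realised herd ADG mean and SD
converge to the specified values.

The three printed summary tables of the underlying trial (input inventory,
livestock performance, per-source contributions) ship as machine-readable
CSV fixtures and load through :func:`load_fixture`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .feed import PASTURE, SILAGE, FeedQualitySeries
from .tier2 import AnimalRecord, WeighingEvent
from .upstream import INVENTORY_KEYS, FarmletInventory, ReseedingSchedule

FARMLETS = ("PP", "WC", "HS")

# Growth-curve shape: relative daily-gain multiplier vs days since entry.
# Post-weaning dip, mid-season peak, finishing plateau.
_SHAPE_DAYS = np.array([0.0, 90.0, 270.0, 480.0, 2000.0])
_SHAPE_VALS = np.array([0.4, 0.4, 2.6, 0.5, 0.5])
_GRID = np.arange(2001, dtype=float)
_SHAPE_GRID = np.interp(_GRID, _SHAPE_DAYS, _SHAPE_VALS)
_SHAPE_CUM = np.concatenate([[0.0], np.cumsum(_SHAPE_GRID)])


def _shape_mean(d0: float, d1: float) -> float:
    """Mean of the growth-curve shape over integer days [d0, d1)."""
    i0, i1 = int(d0), int(min(d1, 2000))
    if i1 <= i0:
        return float(_SHAPE_GRID[min(i0, 2000)])
    return float((_SHAPE_CUM[i1] - _SHAPE_CUM[i0]) / (i1 - i0))


@dataclass(frozen=True)
class HerdSpec:
    """Recipe for one farmlet's herd."""

    farmlet_id: str
    entry_weight_mean: float
    entry_weight_sd: float
    adg_mean: float
    adg_sd: float
    n_animals: int = 30
    target_weight_heifer: float = 555.0
    target_weight_steer: float = 620.0
    sex_ratio: float = 0.5  # fraction steers
    entry_date: date = date(2014, 10, 15)
    housing_windows: tuple[tuple[date, date], ...] = (
        (date(2014, 10, 1), date(2015, 4, 30)),
        (date(2015, 10, 1), date(2016, 4, 30)),
    )
    weighing_interval: tuple[int, int] = (14, 28)
    rng_seed: int = 0
    #: 0 disables the dip/peak/plateau shape (flat growth).
    curve_amplitude: float = 1.0
    #: period-level ADG noise (kg/d), e.g. gut fill and scale error.
    period_noise_sd: float = 0.15
    #: mean ADG advantage of steers over heifers (kg/d); the herd-level mean
    #: and SD contracts are preserved (the between-sex variance is carved out
    #: of adg_sd, and the gap is clamped so it never exceeds adg_sd).
    sex_adg_gap: float = 0.10

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.adg_mean <= 0:
            raise ValueError("adg_mean must be > 0")
        if min(self.entry_weight_sd, self.adg_sd, self.period_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sex_adg_gap < 0:
            raise ValueError("sex_adg_gap must be >= 0")
        lo, hi = self.weighing_interval
        if not (14 <= lo <= hi <= 28):
            raise ValueError("weighing_interval must lie within [14, 28] days")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for a, b in self.housing_windows:
            if b <= a:
                raise ValueError("housing windows must be ordered date intervals")

    def target(self, sex: str) -> float:
        return self.target_weight_steer if sex == "steer" else self.target_weight_heifer

    def location_on(self, day: date) -> str:
        for a, b in self.housing_windows:
            if a <= day <= b:
                return "housing"
        return "pasture"


# ---------------------------------------------------------------------------
# Base-draw calibration.
#
# The stop-at-target rule, the per-animal curve normalisation and the period
# noise all distort an animal's realised whole-record ADG away from its drawn
# base ADG, so the moments of the base draw cannot simply equal the spec
# targets. Rather than hand-tuned correction constants, the generator
# calibrates itself: it simulates a large pilot herd of its own stopping
# process under a fixed internal seed (independent of ``rng_seed``), measures
# the realised herd mean/SD, and applies a two-step correction to the base
# draw. The result is cached per spec family (everything except seed, herd
# size and calendar dates, none of which affect growth moments).
# ---------------------------------------------------------------------------

_PILOT_SEED = 20240915
_PILOT_N = 3000
_CALIBRATION_CACHE: dict[tuple, tuple[float, float]] = {}


def _expected_noise_var(spec: HerdSpec) -> float:
    """First-guess variance the period noise adds to realised whole-record
    ADG at the herd-typical horizon (refined by the pilot calibration)."""
    if spec.period_noise_sd == 0:
        return 0.0
    mean_interval = 0.5 * sum(spec.weighing_interval)
    mean_target = (
        spec.sex_ratio * spec.target_weight_steer
        + (1 - spec.sex_ratio) * spec.target_weight_heifer
    )
    horizon = max((mean_target - spec.entry_weight_mean) / spec.adg_mean, 1.0)
    return spec.period_noise_sd**2 * mean_interval / horizon


def _effective_sex_gap(spec: HerdSpec) -> float:
    """Steer-minus-heifer mean-ADG gap, clamped so the between-sex variance
    it induces never exceeds the herd-level ``adg_sd`` contract."""
    w = spec.sex_ratio * (1.0 - spec.sex_ratio)
    if w == 0.0 or spec.sex_adg_gap == 0.0:
        return 0.0
    cap = spec.adg_sd / np.sqrt(w)
    return float(min(spec.sex_adg_gap, cap))


def _simulate_realized_adg(
    rng: np.random.Generator, spec: HerdSpec, sex: str, entry_w: float,
    base_adg: float,
) -> float:
    """Run one animal's growth/stopping process; return its realised ADG."""
    target = spec.target(sex)
    horizon = max((target - entry_w) / base_adg, 30.0)
    norm = _shape_mean(0.0, horizon)
    lo, hi = spec.weighing_interval
    day, weight = 0, entry_w
    while weight < target and day < 1500:
        interval = int(rng.integers(lo, hi + 1))
        mult = 1.0 + spec.curve_amplitude * (
            _shape_mean(day, day + interval) / norm - 1.0
        )
        gain = (base_adg * mult + rng.normal(0.0, spec.period_noise_sd)
                if spec.period_noise_sd > 0 else base_adg * mult)
        while weight + gain * interval <= 0:
            gain = base_adg * mult + rng.normal(0.0, spec.period_noise_sd)
        day += interval
        weight += gain * interval
    return (weight - entry_w) / day


def _pilot_moments(
    spec: HerdSpec, base_mean: float, base_sd: float, gap: float
) -> tuple[float, float]:
    """Realised (mean, sd) of whole-record ADG for a pilot herd drawn with
    the given base moments under the fixed pilot seed."""
    rng = np.random.default_rng(_PILOT_SEED)
    n_steers = int(round(_PILOT_N * spec.sex_ratio))
    shift = {
        "steer": (1.0 - spec.sex_ratio) * gap,
        "heifer": -spec.sex_ratio * gap,
    }
    vals = np.empty(_PILOT_N)
    for i in range(_PILOT_N):
        sex = "steer" if i < n_steers else "heifer"
        entry_w = rng.normal(spec.entry_weight_mean, spec.entry_weight_sd)
        while entry_w <= 1.0:
            entry_w = rng.normal(spec.entry_weight_mean, spec.entry_weight_sd)
        base = rng.normal(base_mean + shift[sex], base_sd)
        while base <= 0.05:
            base = rng.normal(base_mean + shift[sex], base_sd)
        vals[i] = _simulate_realized_adg(rng, spec, sex, entry_w, base)
    return float(vals.mean()), float(vals.std(ddof=1))


def _calibration_key(spec: HerdSpec) -> tuple:
    return (
        spec.entry_weight_mean, spec.entry_weight_sd, spec.adg_mean,
        spec.adg_sd, spec.target_weight_heifer, spec.target_weight_steer,
        spec.sex_ratio, spec.weighing_interval, spec.curve_amplitude,
        spec.period_noise_sd, spec.sex_adg_gap,
    )


def _base_draw_moments(spec: HerdSpec) -> tuple[float, float]:
    """(mean, sd) for the per-animal base-ADG draw such that the realised
    herd ADG mean and SD converge to the spec values."""
    gap = _effective_sex_gap(spec)
    between_var = spec.sex_ratio * (1.0 - spec.sex_ratio) * gap**2
    if spec.curve_amplitude == 0 and spec.period_noise_sd == 0:
        # Flat noiseless growth: realised ADG equals the draw exactly.
        return spec.adg_mean, float(
            np.sqrt(max(spec.adg_sd**2 - between_var, 0.0))
        )
    key = _calibration_key(spec)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    m = spec.adg_mean
    s = float(np.sqrt(max(
        spec.adg_sd**2 - between_var - _expected_noise_var(spec), 0.0
    )))
    for _ in range(2):
        mr, sr = _pilot_moments(spec, m, s, gap)
        m += spec.adg_mean - mr
        if sr > 0:
            s = max(s + (spec.adg_sd - sr), 0.0)
    _CALIBRATION_CACHE[key] = (m, s)
    return m, s


def generate_herd(spec: HerdSpec) -> list[AnimalRecord]:
    """Generate one farmlet's herd of weighing trajectories.

    Deterministic under ``spec.rng_seed``; negative weight draws are
    regenerated (never emitted) and the trajectory is capped at 1500 days
    for animals that never reach target.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_steers = int(round(spec.n_animals * spec.sex_ratio))
    base_mean, base_sd = _base_draw_moments(spec)
    gap = _effective_sex_gap(spec)
    # Mean shifts preserving the herd mean at any sex ratio.
    sex_shift = {
        "steer": (1.0 - spec.sex_ratio) * gap,
        "heifer": -spec.sex_ratio * gap,
    }

    herd = []
    for i in range(spec.n_animals):
        sex = "steer" if i < n_steers else "heifer"
        target = spec.target(sex)

        entry_w = rng.normal(spec.entry_weight_mean, spec.entry_weight_sd)
        while entry_w <= 1.0:
            entry_w = rng.normal(spec.entry_weight_mean, spec.entry_weight_sd)
        sex_mean = base_mean + sex_shift[sex]
        base_adg = rng.normal(sex_mean, base_sd)
        while base_adg <= 0.05:
            base_adg = rng.normal(sex_mean, base_sd)

        # Normalise the shape over this animal's expected time-to-target so
        # the realised whole-record ADG is an unbiased draw.
        horizon = max((target - entry_w) / base_adg, 30.0)
        norm = _shape_mean(0.0, horizon)

        events = [WeighingEvent(spec.entry_date, entry_w,
                                spec.location_on(spec.entry_date))]
        day, weight = 0, entry_w
        while weight < target and day < 1500:
            lo, hi = spec.weighing_interval
            interval = int(rng.integers(lo, hi + 1))
            mult = 1.0 + spec.curve_amplitude * (
                _shape_mean(day, day + interval) / norm - 1.0
            )
            gain = (base_adg * mult + rng.normal(0.0, spec.period_noise_sd)
                    if spec.period_noise_sd > 0 else base_adg * mult)
            while weight + gain * interval <= 0:
                gain = base_adg * mult + rng.normal(0.0, spec.period_noise_sd)
            day += interval
            weight += gain * interval
            when = spec.entry_date + timedelta(days=day)
            events.append(WeighingEvent(when, weight, spec.location_on(when)))
        herd.append(
            AnimalRecord(f"{spec.farmlet_id}-{i + 1:02d}", spec.farmlet_id,
                         sex, tuple(events))
        )
    return herd


@dataclass(frozen=True)
class FeedSpec:
    """Recipe for one farmlet/feed-type quality series."""

    farmlet_id: str
    feed_type: str
    de_mean: float
    de_sd: float
    cp_mean: float
    cp_sd: float
    seasonal_amplitude: float = 0.0  # percentage points, peak in spring
    sampling_interval: int = 21
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.de_mean < 100 or not 0 < self.cp_mean < 100:
            raise ValueError("de_mean and cp_mean must lie in (0, 100)")
        if min(self.de_sd, self.cp_sd) < 0 or self.seasonal_amplitude < 0:
            raise ValueError("spreads must be >= 0")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")
        if self.feed_type not in (PASTURE, SILAGE):
            raise ValueError("feed_type must be 'pasture' or 'silage'")


_SPRING_PEAK_DOY = 130  # sward quality peaks mid-May


def generate_feed_series(spec: FeedSpec, start: date, end: date
                         ) -> FeedQualitySeries:
    """Seasonal sinusoid plus noise, sampled every ``sampling_interval`` days.

    If the interval is at least the span, a single sample at ``start`` is
    produced. Values are clipped into (0, 100).
    """
    if end <= start:
        raise ValueError("start must precede end")
    rng = np.random.default_rng(spec.rng_seed)
    span = (end - start).days
    offsets = (
        [0] if spec.sampling_interval >= span
        else list(range(0, span, spec.sampling_interval))
    )
    rows = []
    for off in offsets:
        day = start + timedelta(days=off)
        season = np.cos(2 * np.pi * (day.timetuple().tm_yday - _SPRING_PEAK_DOY) / 365.0)
        de = (spec.de_mean + spec.seasonal_amplitude * season
              + rng.normal(0.0, spec.de_sd))
        cp = (spec.cp_mean
              + spec.seasonal_amplitude * (spec.cp_mean / spec.de_mean) * season
              + rng.normal(0.0, spec.cp_sd))
        rows.append(
            (spec.farmlet_id, spec.feed_type, day,
             float(np.clip(de, 0.5, 99.5)), float(np.clip(cp, 0.1, 99.5)))
        )
    return FeedQualitySeries(
        pd.DataFrame(rows, columns=list(FeedQualitySeries.COLUMNS))
    )


# ---------------------------------------------------------------------------
# Packaged fixture tables.
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table1_inventory", "table2_performance", "table3_contributions")


@dataclass(frozen=True)
class FixtureTable:
    """One packaged summary table with label-based numeric lookup."""

    name: str
    df: pd.DataFrame

    def value(self, farmlet: str, variable: str) -> float:
        """Inventory cell (table1)."""
        row = self.df.loc[self.df["variable"] == variable]
        if row.empty:
            raise KeyError(variable)
        return float(row.iloc[0][farmlet])

    def mean(self, farmlet: str, key: str) -> float:
        """Mean cell of table2 (per parameter) or table3 (per source)."""
        col_key = "parameter" if "parameter" in self.df.columns else "source"
        row = self.df.loc[self.df[col_key] == key]
        if row.empty:
            raise KeyError(key)
        v = row.iloc[0][f"{farmlet}_mean"]
        return float(v) if pd.notna(v) else float("nan")

    def sd(self, farmlet: str, key: str) -> float:
        row = self.df.loc[self.df["parameter"] == key]
        if row.empty:
            raise KeyError(key)
        return float(row.iloc[0][f"{farmlet}_sd"])

    def range(self, farmlet: str, source: str) -> Optional[tuple[float, float]]:
        """(min, max) of a table3 source row, or None for an absent entry."""
        row = self.df.loc[self.df["source"] == source]
        if row.empty:
            raise KeyError(source)
        lo, hi = row.iloc[0][f"{farmlet}_min"], row.iloc[0][f"{farmlet}_max"]
        if pd.isna(lo):
            return None
        return float(lo), float(hi)

    @property
    def sources(self) -> list[str]:
        return [s for s in self.df["source"] if s != "Total"]

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False)
        return buf.getvalue()


def load_fixture(name: str) -> FixtureTable:
    """Load one of the packaged summary tables by name."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    path = resources.files("herdlca.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"p_value": str})
    return FixtureTable(name, df)


# ---------------------------------------------------------------------------
# Study-condition defaults built from the fixture tables.
# ---------------------------------------------------------------------------

def study_herd_spec(farmlet: str, seed: int = 0, **overrides) -> HerdSpec:
    """Herd spec matching the trial's per-farmlet performance statistics."""
    t2 = load_fixture("table2_performance")
    spec = HerdSpec(
        farmlet_id=farmlet,
        entry_weight_mean=t2.mean(farmlet, "entry_weight"),
        entry_weight_sd=t2.sd(farmlet, "entry_weight"),
        adg_mean=t2.mean(farmlet, "adg"),
        adg_sd=t2.sd(farmlet, "adg"),
        rng_seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def study_feed_specs(farmlet: str, seed: int = 0) -> list[FeedSpec]:
    """Pasture and silage quality specs around the trial's printed means.

    Spreads are realistic seasonal/analytical values for UK forage series
    (assumed; the trial prints only the annual means).
    """
    t1 = load_fixture("table1_inventory")
    return [
        FeedSpec(farmlet, PASTURE,
                 de_mean=t1.value(farmlet, "pasture_de"), de_sd=2.0,
                 cp_mean=t1.value(farmlet, "pasture_cp"), cp_sd=1.5,
                 seasonal_amplitude=3.0, rng_seed=seed),
        FeedSpec(farmlet, SILAGE,
                 de_mean=t1.value(farmlet, "silage_de"), de_sd=1.5,
                 cp_mean=t1.value(farmlet, "silage_cp"), cp_sd=1.0,
                 seasonal_amplitude=1.0, rng_seed=seed + 1),
    ]


def study_feed_series(farmlets: Sequence[str] = FARMLETS, seed: int = 0,
                      start: date = date(2014, 10, 1),
                      end: date = date(2016, 4, 30)) -> FeedQualitySeries:
    """Combined feed-quality series for several farmlets."""
    frames = []
    for k, farmlet in enumerate(farmlets):
        for spec in study_feed_specs(farmlet, seed=seed + 10 * k):
            frames.append(generate_feed_series(spec, start, end).frame)
    return FeedQualitySeries(pd.concat(frames, ignore_index=True))


# Configured N depositions the pool pathways need but the inventory table
# does not print: annual ewe-flock excretal N on the cattle platform and the
# residue N of reseeded leys (assumed, editable).
_SHEEP_EXCRETA_N_KG = 1800.0
_CROP_RESIDUE_N_KG = {"PP": 0.0, "WC": 150.0, "HS": 150.0}


def study_inventory(farmlet: str) -> FarmletInventory:
    """Farmlet inventory built from the printed input table."""
    t1 = load_fixture("table1_inventory")
    key_map = {
        "fertiliser_n": "fertiliser_n", "fertiliser_p": "fertiliser_p",
        "fertiliser_k": "fertiliser_k", "lime": "lime", "fym_t": "fym",
        "glyphosate": "glyphosate", "fluroxypyr": "fluroxypyr",
        "seed_grass": "seed_grass", "seed_clover": "seed_clover",
        "diesel_l": "diesel", "soybean": "soybean", "straw": "straw",
        "tkm_soybean_sea": "soybean_sea", "tkm_soybean_road": "soybean_road",
        "tkm_straw_road": "straw_road", "tkm_fertiliser_road": "fertiliser_road",
    }
    quantities = {k: t1.value(farmlet, v) for k, v in key_map.items()}
    return FarmletInventory(
        farmlet_id=farmlet,
        area_ha=t1.value(farmlet, "area"),
        quantities=quantities,
        sheep_excreta_n_kg=_SHEEP_EXCRETA_N_KG,
        crop_residue_n_kg=_CROP_RESIDUE_N_KG.get(farmlet, 0.0),
    )


def study_reseeding(farmlet: str) -> Optional[ReseedingSchedule]:
    """Five-yearly renewal for the reseeded systems; none for permanent
    pasture."""
    if farmlet == "PP":
        return None
    return ReseedingSchedule(
        sowing_interval_years=5.0,
        per_event={"diesel_l": 400.0, "glyphosate": 40.0},  # assumed
    )


def herd_to_csv(herd: Iterable[AnimalRecord], path) -> None:
    """Write weighing records in the interchange CSV dialect."""
    rows = [
        (a.animal_id, a.farmlet_id, a.sex, e.date.isoformat(), e.weight_kg,
         e.location)
        for a in herd for e in a.events
    ]
    pd.DataFrame(
        rows,
        columns=["animal_id", "farmlet", "sex", "date", "weight_kg", "location"],
    ).to_csv(path, index=False)


def herd_from_csv(path) -> list[AnimalRecord]:
    """Read weighing records written by :func:`herd_to_csv`."""
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    herd = []
    for (animal_id, farmlet, sex), grp in df.groupby(
        ["animal_id", "farmlet", "sex"], sort=True
    ):
        grp = grp.sort_values("date")
        events = tuple(
            WeighingEvent(r.date, r.weight_kg, r.location)
            for r in grp.itertuples()
        )
        herd.append(AnimalRecord(str(animal_id), str(farmlet), str(sex), events))
    return herd
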