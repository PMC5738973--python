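"""Per-period Tier 2 engine: hand oracles, additivity and the three-animal
worksheet comparison (frozen from scratch/oracle.py, an independent scalar
re-derivation)."""
from datetime import date, timedelta

import numpy as np
import pytest

from herdlca.params import ParameterSet
from herdlca.records import (
    ANIMAL_SOURCES,
    CATTLE_ON_PASTURE,
    ENTERIC_CH4,
    LEACHING,
    MANURE_CH4,
    MANURE_N2O_DIRECT,
    MANURE_N2O_INDIRECT,
)
from herdlca.tier2 import (
    AnimalPeriod,
    AnimalRecord,
    EngineError,
    WeighingEvent,
    animal_emissions,
    enteric_ch4,
    gross_energy_intake,
    manure_ch4,
    manure_n2o,
    n_excretion,
    period_flows,
    periods_from_record,
    rem,
    reg,
)

D0 = date(2015, 5, 1)


def _period(w0, w1, days, location="pasture", de=70.0, cp=20.0):
    return AnimalPeriod(D0, D0 + timedelta(days=days), w0, w1, location, de, cp)


# -- record and period construction ------------------------------------------

def test_weighing_event_validation():
    with pytest.raises(ValueError):
        WeighingEvent(D0, -1.0)
    with pytest.raises(ValueError):
        WeighingEvent(D0, 300.0, "barn")


def test_animal_record_validation():
    e = [WeighingEvent(D0, 300.0), WeighingEvent(D0 + timedelta(days=21), 321.0)]
    a = AnimalRecord("a", "PP", "steer", tuple(e))
    assert a.lwg == pytest.approx(21.0)
    assert a.days_on_platform == 21
    assert a.adg == pytest.approx(1.0)
    with pytest.raises(ValueError, match="weighings"):
        AnimalRecord("a", "PP", "steer", (e[0],))
    with pytest.raises(ValueError, match="increase"):
        AnimalRecord("a", "PP", "steer", (e[1], e[0]))
    with pytest.raises(ValueError, match="sex"):
        AnimalRecord("a", "PP", "bull", tuple(e))


def test_periods_partition_record(const_feed):
    events = tuple(
        WeighingEvent(D0 + timedelta(days=21 * k), 300.0 + 20 * k, "pasture")
        for k in range(5)
    )
    a = AnimalRecord("a", "X", "steer", events)
    periods = periods_from_record(a, const_feed)
    assert len(periods) == 4
    for p, q in zip(periods, periods[1:]):
        assert p.end == q.start  # no gaps, no overlaps
    assert periods[0].start == D0
    assert periods[-1].end == events[-1].date
    assert all(p.de_pct == 77.0 and p.cp_pct == 20.0 for p in periods)


def test_period_with_zero_gain_is_retained(const_feed):
    events = (WeighingEvent(D0, 300.0), WeighingEvent(D0 + timedelta(days=14), 300.0))
    a = AnimalRecord("a", "X", "steer", events)
    (p,) = periods_from_record(a, const_feed)
    assert p.period_adg == 0.0


def test_housed_period_uses_silage(const_feed):
    events = (
        WeighingEvent(D0, 300.0, "housing"),
        WeighingEvent(D0 + timedelta(days=14), 310.0, "pasture"),
    )
    a = AnimalRecord("a", "X", "steer", events)
    (p,) = periods_from_record(a, const_feed)
    assert p.location == "housing"
    assert (p.de_pct, p.cp_pct) == (65.0, 11.5)


# -- scalar formula oracles --------------------------------------------------

def test_rem_reg_match_direct_polynomials():
    de = 70.0
    assert rem(de) == pytest.approx(
        1.123 - 4.092e-3 * de + 1.126e-5 * de**2 - 25.4 / de, rel=1e-12
    )
    assert reg(de) == pytest.approx(
        1.164 - 5.160e-3 * de + 1.308e-5 * de**2 - 37.4 / de, rel=1e-12
    )


def test_maintenance_only_limit(params):
    # [DERIVED] NEm(400 kg) = 0.322*400^0.75 = 28.800555550197295
    p_noact = params.replace(ca_pasture=0.0)
    period = _period(400.0, 400.0, 21)
    ge = gross_energy_intake(period, p_noact, "steer")
    nem = 28.800555550197295
    assert ge == pytest.approx(nem / rem(70.0) / 0.70, rel=1e-9)


def test_full_ge_chain_worksheet(params):
    # [DERIVED] GE(400 kg, 0.8 kg/d, DE 70, steer, pasture) from oracle.py
    period = _period(392.0, 408.0, 20)  # mean 400, adg 0.8
    assert gross_energy_intake(period, params, "steer") == pytest.approx(
        144.3197461429557, rel=1e-9
    )


def test_ge_rejects_bad_de(params):
    with pytest.raises(EngineError):
        gross_energy_intake(_period(400, 408, 10, de=0.0), params, "steer")
    with pytest.raises(EngineError):
        gross_energy_intake(_period(400, 408, 10, de=100.0), params, "steer")


def test_enteric_ch4_values():
    assert enteric_ch4(250.0, 0.0, 10) == 0.0
    assert enteric_ch4(55.65, 100.0, 1) == pytest.approx(1.0, rel=1e-12)
    # [DERIVED] 250*10*0.065/55.65
    assert enteric_ch4(250.0, 6.5, 10) == pytest.approx(2.9200359389038635,
                                                        rel=1e-9)
    with pytest.raises(ValueError):
        enteric_ch4(-1.0, 6.5, 10)


def test_manure_ch4_values(params):
    # fully digestible feed, no urinary or ash path -> zero
    p0 = params.replace(urinary_energy_frac=0.0, ash_frac=0.0)
    assert manure_ch4(100.0, 100.0, 10, p0, "pasture") == pytest.approx(0.0)
    # [DERIVED] VS=1 kg/day at ge=18.45, de=0; housed: 0.18*0.67*0.20 = 0.02412
    assert manure_ch4(18.45, 0.0, 1, p0, "housing") == pytest.approx(
        0.02412, rel=1e-9
    )


def test_n_excretion_values(params):
    period = _period(392.0, 408.0, 20)
    assert n_excretion(250.0, 0.0, period, params, "steer") == 0.0
    # adg <= 0 -> no retention: N_ex = intake * days
    loss = _period(408.0, 392.0, 10)
    n_int = (250.0 / 18.45) * (20.0 / 100.0) / 6.25
    assert n_excretion(250.0, 20.0, loss, params, "steer") == pytest.approx(
        n_int * 10, rel=1e-12
    )
    # [DERIVED] worked worksheet value at (ge=250, cp=20, adg=0.8, 400 kg, 10 d)
    p10 = AnimalPeriod(D0, D0 + timedelta(days=10), 396.0, 404.0, "pasture",
                       70.0, 20.0)
    assert n_excretion(250.0, 20.0, p10, params, "steer") == pytest.approx(
        4.13258669347404, rel=1e-9
    )


def test_manure_n2o_pathways(params):
    zero = manure_n2o(0.0, "housing", params)
    assert all(r.mass_kg == 0.0 for r in zero)
    # [DERIVED] 100 kg housed N * 0.01 * 44/28
    recs = {r.source: r.mass_kg for r in manure_n2o(100.0, "housing", params)}
    assert recs[MANURE_N2O_DIRECT] == pytest.approx(1.5714285714285714, rel=1e-9)
    assert recs[MANURE_N2O_INDIRECT] == pytest.approx(
        100.0 * 0.30 * 0.01 * 44 / 28, rel=1e-9
    )
    grazed = {r.source: r.mass_kg for r in manure_n2o(100.0, "pasture", params)}
    assert set(grazed) == {CATTLE_ON_PASTURE, LEACHING}
    assert grazed[CATTLE_ON_PASTURE] == pytest.approx(100 * 0.02 * 44 / 28)
    assert grazed[LEACHING] == pytest.approx(100 * 0.30 * 0.0075 * 44 / 28)
    # all factors zero -> all zero
    pz = params.replace(ef3_deep_bedding=0.0, frac_gas_ms=0.0)
    assert all(r.mass_kg == 0.0 for r in manure_n2o(50.0, "housing", pz))


def test_monotonicity(params):
    assert enteric_ch4(260.0, 6.5, 10) > enteric_ch4(250.0, 6.5, 10)
    lo = manure_ch4(250.0, 60.0, 10, params, "housing")
    hi = manure_ch4(250.0, 75.0, 10, params, "housing")
    assert hi < lo  # more digestible -> less VS -> less manure CH4


# -- whole-animal evaluation -------------------------------------------------

def _source_totals(a, feed, params):
    out = {}
    for r in animal_emissions(a, feed, params):
        out[r.source] = out.get(r.source, 0.0) + r.mass_kg
    return out


def test_exact_additivity_at_constant_weight(const_feed, params):
    # identical per-day flows in each sub-period -> exact additivity
    whole = AnimalRecord("w", "X", "steer", (
        WeighingEvent(D0, 300.0), WeighingEvent(D0 + timedelta(days=28), 300.0),
    ))
    split = AnimalRecord("s", "X", "steer", (
        WeighingEvent(D0, 300.0),
        WeighingEvent(D0 + timedelta(days=14), 300.0),
        WeighingEvent(D0 + timedelta(days=28), 300.0),
    ))
    tw = _source_totals(whole, const_feed, params)
    ts = _source_totals(split, const_feed, params)
    assert set(tw) == set(ts)
    for k in tw:
        assert tw[k] == pytest.approx(ts[k], rel=1e-12)


def test_near_additivity_for_growing_animal(const_feed, params):
    # repartitioning a growing period shifts per-period mean weights; W^0.75
    # concavity makes the split sum slightly smaller, but only slightly
    whole = AnimalRecord("w", "X", "steer", (
        WeighingEvent(D0, 300.0), WeighingEvent(D0 + timedelta(days=28), 328.0),
    ))
    split = AnimalRecord("s", "X", "steer", (
        WeighingEvent(D0, 300.0),
        WeighingEvent(D0 + timedelta(days=14), 314.0),
        WeighingEvent(D0 + timedelta(days=28), 328.0),
    ))
    tw = _source_totals(whole, const_feed, params)
    ts = _source_totals(split, const_feed, params)
    assert set(tw) == set(ts)
    for k in tw:
        assert ts[k] <= tw[k]
        assert tw[k] == pytest.approx(ts[k], rel=1e-3)


def test_emitted_sources_are_registry_animal_sources(toy_herd, const_feed,
                                                     params):
    for a in toy_herd:
        for r in animal_emissions(a, const_feed, params):
            assert r.source in ANIMAL_SOURCES
            assert r.owner_id == a.animal_id
            assert np.isfinite(r.mass_kg) and r.mass_kg > 0


# [DERIVED] three-animal worksheet oracle (scratch/oracle.py), 6 s.f.
_ORACLE = {
    "T1": {
        ENTERIC_CH4: 6.26584593, MANURE_CH4: 1.433051389,
        MANURE_N2O_DIRECT: 0.0403078938, MANURE_N2O_INDIRECT: 0.01209236814,
        CATTLE_ON_PASTURE: 0.1118311475, LEACHING: 0.0125810041,
    },
    "T2": {
        ENTERIC_CH4: 4.994398694, MANURE_CH4: 0.06942846271,
        MANURE_N2O_DIRECT: 0.0, MANURE_N2O_INDIRECT: 0.0,
        CATTLE_ON_PASTURE: 0.2106024051, LEACHING: 0.02369277058,
    },
    "T3": {
        ENTERIC_CH4: 4.987394955, MANURE_CH4: 0.8064338723,
        MANURE_N2O_DIRECT: 0.02550999657, MANURE_N2O_INDIRECT: 0.007652998972,
        CATTLE_ON_PASTURE: 0.1264750273, LEACHING: 0.01422844057,
    },
}


def test_toy_herd_matches_worksheet_oracle(toy_herd, const_feed, params):
    for a in toy_herd:
        got = dict.fromkeys(_ORACLE[a.animal_id], 0.0)
        for r in animal_emissions(a, const_feed, params):
            got[r.source] += r.mass_kg
        for source, want in _ORACLE[a.animal_id].items():
            if want == 0.0:
                assert got[source] == 0.0
            else:
                assert got[source] == pytest.approx(want, rel=1e-6), (
                    a.animal_id, source
                )


def test_vectorised_flows_match_scalar_path(toy_herd, const_feed, params):
    a = toy_herd[0]
    periods = periods_from_record(a, const_feed)
    arrays = {
        "days": np.array([p.days for p in periods], dtype=float),
        "mean_weight": np.array([p.mean_weight for p in periods]),
        "adg": np.array([p.period_adg for p in periods]),
        "de_pct": np.array([p.de_pct for p in periods]),
        "cp_pct": np.array([p.cp_pct for p in periods]),
        "is_housed": np.array([p.location == "housing" for p in periods]),
    }
    flows = period_flows(
        **arrays, c_sex=params.c_growth("steer"),
        mature_w=params.mature_weight("steer"), p=params,
    )
    for i, p in enumerate(periods):
        ge = gross_energy_intake(p, params, "steer")
        assert flows["ge"][i] == pytest.approx(ge, rel=1e-12)
        assert flows[ENTERIC_CH4][i] == pytest.approx(
            enteric_ch4(ge, 6.5, p.days), rel=1e-12
        )
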