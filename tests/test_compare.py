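"""Representative animal, aggregation bias, Monte Carlo and interpretation."""
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herdlca.compare import (
    ComparisonReport,
    Distribution,
    HerdSummary,
    MCResult,
    MCSpec,
    aggregation_bias,
    interpret,
    monte_carlo,
    percent_spread,
    representative_animal,
)

D0 = date(2014, 10, 15)


# -- herd summary and representative trajectory ------------------------------

def test_herd_summary_from_toy_herd(toy_herd):
    s = HerdSummary.from_herd(toy_herd)
    assert s.farmlet_id == "X"
    assert s.entry_weight == pytest.approx((300 + 280 + 350) / 3)
    assert s.finishing_weight == pytest.approx((335 + 308.2 + 365) / 3)
    assert s.total_growth == pytest.approx((35 + 28.2 + 15) / 3)
    assert s.days_on_platform == pytest.approx((49 + 42 + 42) / 3)


def test_representative_animal_trajectory():
    s = HerdSummary("X", 300.0, 400.0, 100.0, 100.0, 1.0)
    rep = representative_animal(s, entry_date=D0, weighing_interval=21)
    assert rep.farmlet_id == "X"
    assert rep.entry_weight == 300.0
    assert rep.exit_weight == pytest.approx(400.0)
    assert rep.days_on_platform == 100
    assert rep.adg == pytest.approx(1.0)
    # regular 21-day schedule closed by the final day
    offsets = [(e.date - D0).days for e in rep.events]
    assert offsets == [0, 21, 42, 63, 84, 100]
    # weights grow linearly at the summary ADG
    for e, t in zip(rep.events, offsets):
        assert e.weight_kg == pytest.approx(300.0 + 1.0 * t)


def test_representative_animal_housing_windows():
    s = HerdSummary("X", 300.0, 400.0, 100.0, 100.0, 1.0)
    rep = representative_animal(
        s, entry_date=D0,
        housing_windows=((date(2014, 10, 1), date(2014, 11, 10)),),
    )
    locs = {(e.date - D0).days: e.location for e in rep.events}
    assert locs[0] == "housing" and locs[21] == "housing"
    assert locs[42] == "pasture"


def test_aggregation_bias_two_animal_oracle():
    # [DERIVED] burden 100 kg each; lwg 100 and 300 kg -> EIs 1.0 and 1/3,
    # mean 2/3; representative lwg 200 -> EI 0.5; bias 1/6
    eis = [100.0 / 100.0, 100.0 / 300.0]
    assert np.mean(eis) == pytest.approx(2.0 / 3.0)
    rep_ei = 100.0 / 200.0
    assert aggregation_bias(eis, rep_ei) == pytest.approx(1.0 / 6.0, rel=1e-12)
    with pytest.raises(ValueError):
        aggregation_bias([], 1.0)


@given(
    lwgs=st.lists(st.floats(min_value=5.0, max_value=500.0), min_size=2,
                  max_size=30),
    burden=st.floats(min_value=1.0, max_value=5000.0),
)
def test_jensen_bias_nonnegative_for_invariant_burden(lwgs, burden):
    """Convexity: mean of per-animal EIs >= EI of the mean animal whenever
    every animal carries the same burden."""
    eis = [burden / g for g in lwgs]
    rep = burden / float(np.mean(lwgs))
    assert aggregation_bias(eis, rep) >= -1e-12


def test_percent_spread():
    assert percent_spread(10.0, 15.0) == pytest.approx(50.0)
    assert percent_spread(10.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        percent_spread(0.0, 5.0)


# -- distributions and Monte Carlo -------------------------------------------

def test_distribution_validation():
    with pytest.raises(ValueError):
        Distribution("beta", 1.0, 0.1)
    with pytest.raises(ValueError):
        Distribution("normal", 1.0, -0.1)
    with pytest.raises(ValueError):
        Distribution("lognormal", 1.0, 0.9)
    with pytest.raises(ValueError):
        Distribution("lognormal", -1.0, 1.2)


def test_degenerate_distributions_return_center():
    rng = np.random.default_rng(0)
    assert Distribution("normal", 6.5, 0.0).draw(rng) == 6.5
    assert Distribution("lognormal", 6.5, 1.0).draw(rng) == pytest.approx(6.5)
    assert Distribution("uniform", 6.5, 0.0).draw(rng) == pytest.approx(6.5)


def test_uniform_bounds_and_lognormal_median():
    rng = np.random.default_rng(1)
    u = Distribution("uniform", 10.0, 2.0)
    draws = np.array([u.draw(rng) for _ in range(500)])
    assert draws.min() >= 8.0 and draws.max() <= 12.0
    ln = Distribution("lognormal", 10.0, 1.5)
    draws = np.array([ln.draw(rng) for _ in range(4000)])
    assert np.all(draws > 0)
    assert np.median(draws) == pytest.approx(10.0, rel=0.05)


def test_mcspec_validation():
    with pytest.raises(ValueError):
        MCSpec({}, n_iterations=0)
    with pytest.raises(ValueError):
        MCSpec({"x": 3.0})


def _echo_model(overrides):
    return {"A": overrides["x"], "B": 2 * overrides["x"]}


def test_monte_carlo_deterministic_and_shaped():
    spec = MCSpec({"x": Distribution("normal", 5.0, 1.0)}, n_iterations=40,
                  rng_seed=7)
    r1 = monte_carlo(_echo_model, spec)
    r2 = monte_carlo(_echo_model, spec)
    pd.testing.assert_frame_equal(r1.iterates, r2.iterates)
    assert r1.systems == ["A", "B"]
    assert len(r1.values("A")) == 40
    np.testing.assert_allclose(r1.values("B"), 2 * r1.values("A"))


def test_mc_result_summaries(tmp_path):
    spec = MCSpec({"x": Distribution("normal", 5.0, 1.0)}, n_iterations=200,
                  rng_seed=3)
    res = monte_carlo(_echo_model, spec)
    lo, hi = res.interval("A")
    assert lo < res.median("A") < hi
    # B is strictly twice A in every iterate
    frac, p = res.exceedance("B", "A")
    assert frac == 1.0 and p == 0.0
    frac_aa, p_aa = res.exceedance("A", "A")
    assert frac_aa == 0.0 and p_aa == 0.0
    out = tmp_path / "iter.csv"
    res.to_csv(out)
    back = pd.read_csv(out)
    assert list(back.columns) == ["iteration", "system", "ei"]
    assert len(back) == 400


# -- interpretation ----------------------------------------------------------

def _frame(rows):
    return pd.DataFrame(
        rows, columns=["system", "animal_id", "sex", "adg", "lwg", "days", "ei"]
    )


def test_interpret_identical_groups_give_null_statistics():
    rows = []
    for sysname in ("A", "B"):
        for i, (adg, ei) in enumerate([(0.6, 1.0), (0.8, 2.0), (1.0, 3.0)]):
            sex = "steer" if i % 2 == 0 else "heifer"
            rows.append((sysname, f"{sysname}{i}", sex, adg, adg * 100, 100, ei))
    rep = interpret(_frame(rows))
    assert rep.anova["ei"].statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.anova["ei"].pvalue == pytest.approx(1.0)
    t = rep.pairwise_ei[("A", "B")]
    assert t.statistic == pytest.approx(0.0, abs=1e-12)
    assert t.pvalue == pytest.approx(1.0)


def test_interpret_correlation_matches_pearson_oracle():
    # [DERIVED] pearsonr([1..5], [2,1,4,3,7]) = 0.824163383692134
    rows = [
        ("A", f"a{i}", "steer", float(i + 1), 100.0, 100, y)
        for i, y in enumerate([2.0, 1.0, 4.0, 3.0, 7.0])
    ]
    rows += [("B", f"b{i}", "steer", 1.0 + 0.1 * i, 100.0, 100, 5.0 - 0.5 * i)
             for i in range(4)]
    rep = interpret(_frame(rows))
    assert rep.correlations["A"].statistic == pytest.approx(
        0.824163383692134, rel=1e-9
    )
    # exact linear negative relation -> r = -1
    assert rep.correlations["B"].statistic == pytest.approx(-1.0, abs=1e-9)


def test_interpret_per_system_summary_and_sex_contrast():
    rows = [
        ("A", "s1", "steer", 1.0, 110.0, 110, 10.0),
        ("A", "s2", "steer", 1.1, 121.0, 110, 11.0),
        ("A", "h1", "heifer", 0.8, 88.0, 110, 14.0),
        ("A", "h2", "heifer", 0.9, 99.0, 110, 15.0),
        ("B", "s3", "steer", 1.0, 100.0, 100, 12.0),
        ("B", "s4", "steer", 1.2, 120.0, 100, 13.0),
        ("B", "h3", "heifer", 0.7, 70.0, 100, 16.0),
        ("B", "h4", "heifer", 0.8, 80.0, 100, 18.0),
    ]
    rep = interpret(_frame(rows))
    a = rep.per_system["A"]
    assert a["n"] == 4
    assert a["best_ei"] == 10.0 and a["worst_ei"] == 15.0
    assert a["percent_spread"] == pytest.approx(50.0)
    c = rep.sex_contrasts["A"]["ei"]
    assert c["difference"] == pytest.approx(10.5 - 14.5)
    assert c["pvalue"] < 0.05


def test_interpret_degenerate_groups_warn_not_crash(caplog):
    rows = [
        ("A", "a1", "steer", 1.0, 100.0, 100, 10.0),
        ("A", "a2", "steer", 1.0, 100.0, 100, 10.0),
        ("B", "b1", "heifer", 0.9, 90.0, 100, 12.0),
    ]
    with caplog.at_level("WARNING"):
        rep = interpret(_frame(rows))
    assert rep.warnings  # tests skipped, reported
    assert ("A", "B") not in rep.pairwise_ei
    assert isinstance(rep.to_dict(), dict)
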