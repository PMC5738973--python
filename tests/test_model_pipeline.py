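"""Model facade, fast-evaluation path, Monte Carlo hooks, pipeline and CLI."""
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from herdlca.cli import main as cli_main
from herdlca.compare import Distribution, MCSpec
from herdlca.model import ECONOMIC_BASIS, MASS_BASIS, HerdLCAModel
from herdlca.pipeline import (
    RunConfig,
    StageError,
    inventories_from_csv,
    load_mc_spec,
    run_pipeline,
)
from herdlca.records import CROP_RESIDUES, SOURCE_ORDER
from herdlca.reporting import ReportDocument
from herdlca.synthetic import load_fixture

CONFIGS = Path(__file__).resolve().parents[1] / "src" / "herdlca" / "configs"


@pytest.fixture(scope="module")
def model():
    return HerdLCAModel.from_synthetic(seed=42, n_animals=30)


@pytest.fixture(scope="module")
def results(model):
    return model.fit()


# -- fitted results ----------------------------------------------------------

def test_animals_frame_shape(results):
    df = results.animals
    assert set(df["system"]) == {"PP", "WC", "HS"}
    core = ["system", "animal_id", "sex", "entry_weight", "exit_weight",
            "lwg", "days", "adg", "total_co2e", "ei"]
    assert list(df.columns) == core + list(SOURCE_ORDER)
    assert 85 <= len(df) <= 90  # rare non-finishers may be excluded
    assert (df["ei"] > 0).all() and np.isfinite(df["ei"]).all()
    assert (df["lwg"] > 0).all()


def test_breakdown_columns_sum_to_total(results):
    df = results.animals
    sums = df[list(SOURCE_ORDER)].sum(axis=1)
    np.testing.assert_allclose(sums, df["total_co2e"], rtol=1e-9)
    np.testing.assert_allclose(df["ei"] * df["lwg"], df["total_co2e"],
                               rtol=1e-9)


def test_conservation_within_tolerance(results):
    for s in ("PP", "WC", "HS"):
        assert results.conservation_error(s) <= 1e-9


def test_system_breakdown_table(results):
    tab = results.system_breakdown()
    assert list(tab["source"]) == list(SOURCE_ORDER) + ["Total"]
    # crop residues only exist on the reseeded systems
    cr = tab[tab["source"] == CROP_RESIDUES].iloc[0]
    assert np.isnan(cr["PP_mean"]) and cr["WC_mean"] > 0 and cr["HS_mean"] > 0
    total = tab[tab["source"] == "Total"].iloc[0]
    pp = results.animals[results.animals["system"] == "PP"]
    assert total["PP_mean"] == pytest.approx(pp["ei"].mean())
    assert total["PP_min"] == pytest.approx(pp["ei"].min())
    assert total["PP_max"] == pytest.approx(pp["ei"].max())
    # per-system source means stack to the mean EI
    means = tab[tab["source"] != "Total"]["PP_mean"].dropna().sum()
    per_kg = (pp[list(SOURCE_ORDER)].div(pp["lwg"], axis=0)).sum(axis=1)
    assert means == pytest.approx(per_kg.mean(), rel=1e-9)


def test_representative_entries(results):
    rep = results.representative()
    for s in ("PP", "WC", "HS"):
        e = rep[s]
        df = results.animals[results.animals["system"] == s]
        assert e["mean_individual_ei"] == pytest.approx(df["ei"].mean())
        assert e["bias"] == pytest.approx(
            e["mean_individual_ei"] - e["representative_ei"], rel=1e-12
        )
        assert e["representative_ei"] > 0


def test_fast_path_matches_fit(model, results):
    """The vectorised evaluation used by Monte Carlo reproduces the
    fitted per-animal allocated totals exactly."""
    for s in ("PP", "WC", "HS"):
        cache = model._cache[s]
        totals = model._system_totals(cache, model.params, results.gwp,
                                      results.cattle_share)
        fitted = {r.animal_id: r.total_co2e_kg for r in results.results_for(s)}
        for aid, t in zip(cache.animal_ids, totals):
            if aid in fitted:  # excluded animals have no EIResult
                assert t == pytest.approx(fitted[aid], rel=1e-9), (s, aid)


def test_gwp_and_allocation_variants(model, results):
    ar4 = model.fit(gwp="ar4")
    assert not np.allclose(
        ar4.animals["total_co2e"], results.animals["total_co2e"]
    )
    mass = model.fit(allocation=MASS_BASIS)
    assert mass.cattle_share == pytest.approx(0.72)
    assert results.cattle_share == pytest.approx(0.78)
    # the pre-allocation system total is allocation-invariant and conserved
    for s in ("PP", "WC", "HS"):
        a, b = results._sys[s], mass._sys[s]
        assert a["system_total_co2e"] == pytest.approx(b["system_total_co2e"],
                                                       rel=1e-12)
        assert mass.conservation_error(s) <= 1e-9
        # more to the sheep -> less on the cattle
        assert b["cattle_total_co2e"] < a["cattle_total_co2e"]


def test_summary_text(results):
    text = results.summary()
    for token in ("Emissions intensity", "PP", "WC", "HS", "economic"):
        assert token in text


# -- Monte Carlo through the model -------------------------------------------

def test_mc_zero_spread_reproduces_deterministic_fit(results):
    spec = MCSpec({"ym_pasture": Distribution("normal", 6.5, 0.0)},
                  n_iterations=3, rng_seed=0)
    res = results.monte_carlo(spec)
    for s in ("PP", "WC", "HS"):
        df = results.animals[results.animals["system"] == s]
        np.testing.assert_allclose(res.values(s), df["ei"].mean(), rtol=1e-9)


def test_mc_interval_widens_with_spread(results):
    narrow = MCSpec({"ym_pasture": Distribution("normal", 6.5, 0.2)},
                    n_iterations=60, rng_seed=1)
    wide = MCSpec({"ym_pasture": Distribution("normal", 6.5, 0.6)},
                  n_iterations=60, rng_seed=1)
    ni = results.monte_carlo(narrow).interval("PP")
    wi = results.monte_carlo(wide).interval("PP")
    assert wi[1] - wi[0] > ni[1] - ni[0]


def test_mc_best_worst_targets(results):
    spec = MCSpec({"ym_pasture": Distribution("normal", 6.5, 0.0)},
                  n_iterations=2, rng_seed=0)
    best = results.monte_carlo(spec, target="best")
    worst = results.monte_carlo(spec, target="worst")
    for s in ("PP", "WC", "HS"):
        df = results.animals[results.animals["system"] == s]
        assert best.values(s)[0] == pytest.approx(df["ei"].min(), rel=1e-9)
        assert worst.values(s)[0] == pytest.approx(df["ei"].max(), rel=1e-9)


def test_mc_rejects_unknown_parameter(results):
    spec = MCSpec({"warp_factor": Distribution("normal", 1.0, 0.1)})
    with pytest.raises(ValueError, match="warp_factor"):
        results.monte_carlo(spec)
    with pytest.raises(ValueError, match="target"):
        results.monte_carlo(
            MCSpec({"ym_pasture": Distribution("normal", 6.5, 0.0)}),
            target="median",
        )


# -- pipeline and CLI --------------------------------------------------------

def test_run_config_validation():
    with pytest.raises(ValueError, match="together"):
        RunConfig(herd_csv="herd.csv").validate()
    with pytest.raises(ValueError, match="gwp"):
        RunConfig(gwp="ar6").validate()
    with pytest.raises(ValueError, match="allocation"):
        RunConfig(allocation="energy").validate()
    RunConfig().validate()


def test_inventories_from_csv(tmp_path):
    t1 = load_fixture("table1_inventory")
    path = tmp_path / "inv.csv"
    path.write_text(t1.to_csv_text())
    config = RunConfig(crop_residue_n_kg={"WC": 150.0})
    invs = inventories_from_csv(path, config)
    assert set(invs) == {"PP", "WC", "HS"}
    assert invs["PP"].get("fertiliser_n") == 4951.0
    assert invs["PP"].sheep_excreta_n_kg == 1800.0
    assert invs["WC"].crop_residue_n_kg == 150.0
    assert invs["PP"].crop_residue_n_kg == 0.0


def test_load_mc_spec_from_shipped_config():
    spec = load_mc_spec(CONFIGS / "default_mc.yaml", seed=9)
    assert spec.rng_seed == 9
    assert spec.n_iterations >= 1
    assert spec.distributions


def test_run_pipeline_outputs_and_determinism(tmp_path):
    mc_yaml = tmp_path / "mc.yaml"
    mc_yaml.write_text(
        "n_iterations: 8\n"
        "distributions:\n"
        "  ym_pasture: {kind: normal, center: 6.5, spread: 0.3}\n"
    )
    out = tmp_path / "run"
    config = RunConfig(out_dir=str(out), seed=7, n_animals=8,
                       mc_yaml=str(mc_yaml), log_level="WARNING")
    paths = run_pipeline(config)
    for key in ("animals", "system_breakdown", "report_json", "report_txt",
                "manifest", "mc_iterates"):
        assert Path(paths[key]).is_file(), key
    doc = ReportDocument.model_validate_json(
        Path(paths["report_json"]).read_text()
    )
    assert doc.manifest.seed == 7
    assert doc.monte_carlo is not None and set(doc.monte_carlo) == {
        "PP", "WC", "HS"
    }
    first = {k: Path(p).read_bytes() for k, p in paths.items()}
    again = run_pipeline(config)
    for k, p in again.items():
        assert Path(p).read_bytes() == first[k], f"{k} not reproducible"


def test_cli_run_and_exit_codes(tmp_path):
    runner = CliRunner()
    out = tmp_path / "cli_out"
    ok = runner.invoke(
        cli_main,
        ["run", "--seed", "3", "--n-animals", "6", "--out", str(out),
         "--log-level", "WARNING"],
    )
    assert ok.exit_code == 0, ok.output
    assert (out / "report.json").is_file()

    # herd without feed/inventory -> configuration error, exit 1
    lone = tmp_path / "herd.csv"
    lone.write_text("animal_id,farmlet,sex,date,weight_kg,location\n")
    bad_cfg = runner.invoke(cli_main, ["run", "--herd", str(lone)])
    assert bad_cfg.exit_code == 1

    # malformed inputs supplied together -> stage failure, exit 2
    feed = tmp_path / "feed.csv"
    feed.write_text("nonsense\n")
    inv = tmp_path / "inv.csv"
    inv.write_text("nonsense\n")
    broken = runner.invoke(
        cli_main,
        ["run", "--herd", str(lone), "--feed", str(feed),
         "--inventory", str(inv), "--out", str(tmp_path / "x")],
    )
    assert broken.exit_code == 2
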