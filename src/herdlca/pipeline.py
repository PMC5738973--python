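"""End-to-end orchestration: data (or synthetic specs) in, report bundle out.

A :class:`RunConfig` names either input files (herd/feed/inventory CSVs) or a
synthetic seed, plus the parameter set, GWP set, allocation basis and an
optional Monte Carlo recipe. :func:`run_pipeline` fits the model, verifies
emission conservation, and writes the per-animal table, the per-source
system breakdown, the comparison report (JSON, schema-validated, plus a text
rendering) and a manifest carrying the seed and configuration hash. Outputs
are fully deterministic: identical config and seed give identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .allocation import AllocationBasis
from .compare import Distribution, MCSpec
from .model import ECONOMIC_BASIS, MASS_BASIS, HerdLCAModel, HerdLCAResults
from .params import ParameterSet
from .reporting import (
    Manifest,
    MCSystemEntry,
    ReportDocument,
    TestStat,
    config_hash,
    summarize_distributions,
)
from .upstream import FarmletInventory, UpstreamEFTable

logger = logging.getLogger(__name__)

#: conservation tolerance (relative) enforced on every run
CONSERVATION_RTOL = 1e-9


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str = "herdlca_out"
    seed: int = 0
    # data inputs (all three or none; none means synthetic herds)
    herd_csv: Optional[str] = None
    feed_csv: Optional[str] = None
    inventory_csv: Optional[str] = None
    params_yaml: Optional[str] = None
    gwp: str = "ar5"
    allocation: str = "economic"
    mc_yaml: Optional[str] = None
    representative: bool = True
    n_animals: int = 30
    log_level: str = "INFO"
    # per-farmlet configured N depositions for file-based inventories
    sheep_excreta_n_kg: float = 1800.0
    crop_residue_n_kg: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        paths = (self.herd_csv, self.feed_csv, self.inventory_csv)
        some, every = any(p for p in paths), all(p for p in paths)
        if some and not every:
            raise ValueError(
                "herd_csv, feed_csv and inventory_csv must be given together "
                "(or all omitted for a synthetic run)"
            )
        if self.gwp not in ("ar5", "ar4"):
            raise ValueError("gwp must be 'ar5' or 'ar4'")
        if self.allocation not in ("economic", "mass"):
            raise ValueError("allocation must be 'economic' or 'mass'")

    @property
    def synthetic(self) -> bool:
        return self.herd_csv is None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["crop_residue_n_kg"] = dict(d["crop_residue_n_kg"])
        return d


def inventories_from_csv(
    path, config: RunConfig
) -> dict[str, FarmletInventory]:
    """Read a farmlet-inventory CSV in the packaged table dialect
    (variable, label, unit, one column per farmlet)."""
    df = pd.read_csv(path)
    key_map = {
        "fertiliser_n": "fertiliser_n", "fertiliser_p": "fertiliser_p",
        "fertiliser_k": "fertiliser_k", "lime": "lime", "fym_t": "fym",
        "glyphosate": "glyphosate", "fluroxypyr": "fluroxypyr",
        "seed_grass": "seed_grass", "seed_clover": "seed_clover",
        "diesel_l": "diesel", "soybean": "soybean", "straw": "straw",
        "tkm_soybean_sea": "soybean_sea", "tkm_soybean_road": "soybean_road",
        "tkm_straw_road": "straw_road", "tkm_fertiliser_road": "fertiliser_road",
    }
    farmlets = [c for c in df.columns if c not in ("variable", "label", "unit")]
    by_var = df.set_index("variable")
    out = {}
    for f in farmlets:
        quantities = {
            k: float(by_var.at[v, f]) for k, v in key_map.items()
            if v in by_var.index
        }
        out[f] = FarmletInventory(
            farmlet_id=f,
            area_ha=float(by_var.at["area", f]) if "area" in by_var.index else 0.0,
            quantities=quantities,
            sheep_excreta_n_kg=config.sheep_excreta_n_kg,
            crop_residue_n_kg=float(config.crop_residue_n_kg.get(f, 0.0)),
        )
    return out


def load_mc_spec(path, seed: int) -> MCSpec:
    """Read a Monte Carlo recipe from YAML.

    Layout: ``n_iterations`` plus a ``distributions`` block of
    ``name: {kind, center, spread}`` entries.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    dists = {
        name: Distribution(d["kind"], float(d["center"]), float(d["spread"]))
        for name, d in doc.get("distributions", {}).items()
    }
    return MCSpec(
        distributions=dists,
        n_iterations=int(doc.get("n_iterations", 1000)),
        rng_seed=seed,
    )


def _build_model(config: RunConfig) -> HerdLCAModel:
    params = (
        ParameterSet.from_yaml(config.params_yaml)
        if config.params_yaml else ParameterSet()
    )
    allocation = ECONOMIC_BASIS if config.allocation == "economic" else MASS_BASIS
    if config.synthetic:
        return HerdLCAModel.from_synthetic(
            seed=config.seed, n_animals=config.n_animals, params=params,
            allocation=allocation, gwp=config.gwp,
        )
    return HerdLCAModel.from_csv(
        config.herd_csv, config.feed_csv,
        inventories_from_csv(config.inventory_csv, config),
        params=params, allocation=allocation, gwp=config.gwp,
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def build_report(
    config: RunConfig, results: HerdLCAResults, mc_result=None
) -> ReportDocument:
    interp = results.interpret()
    rep = results.representative()
    doc = ReportDocument(
        manifest=Manifest(
            version=__version__,
            seed=config.seed,
            config_hash=config_hash(config.to_dict()),
            gwp=results.gwp.name,
            allocation=results.allocation.method,
            cattle_share=results.cattle_share,
        ),
        per_system=interp.per_system,
        representative=rep,
        anova={k: v.to_dict() for k, v in interp.anova.items()},
        pairwise_ei={
            f"{a}_vs_{b}": v.to_dict() for (a, b), v in interp.pairwise_ei.items()
        },
        correlations={k: v.to_dict() for k, v in interp.correlations.items()},
        sex_contrasts=interp.sex_contrasts,
        distributions=summarize_distributions(results.animals),
        warnings=interp.warnings,
    )
    if mc_result is not None:
        systems = mc_result.systems
        doc = doc.model_copy(
            update={
                "monte_carlo": {
                    s: MCSystemEntry(
                        median=mc_result.median(s),
                        p2_5=mc_result.interval(s)[0],
                        p97_5=mc_result.interval(s)[1],
                    )
                    for s in systems
                },
                "mc_pairwise": {
                    f"{a}_vs_{b}": TestStat(
                        statistic=mc_result.exceedance(a, b)[0],
                        pvalue=mc_result.exceedance(a, b)[1],
                    )
                    for i, a in enumerate(systems)
                    for b in systems[i + 1:]
                },
            }
        )
    return doc


def _report_text(doc: ReportDocument, results: HerdLCAResults) -> str:
    lines = [results.summary(), ""]
    if doc.anova:
        lines.append("One-way ANOVA across systems:")
        for var, t in doc.anova.items():
            lines.append(f"  {var}: F = {t.statistic:.2f}, p = {t.pvalue:.4g}")
    if doc.correlations:
        lines.append("Pearson r (EI vs ADG) per system:")
        for s, t in doc.correlations.items():
            lines.append(f"  {s}: r = {t.statistic:.3f}, p = {t.pvalue:.4g}")
    if doc.monte_carlo:
        lines.append("Monte Carlo 95% intervals (EI):")
        for s, e in doc.monte_carlo.items():
            lines.append(
                f"  {s}: median {e.median:.2f} [{e.p2_5:.2f}, {e.p97_5:.2f}]"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the paths of everything written."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = _stage("build")(_build_model)(config)
    results: HerdLCAResults = _stage("fit")(model.fit)()

    for s in model.systems:
        err = results.conservation_error(s)
        if err > CONSERVATION_RTOL:
            raise StageError(
                f"stage 'conservation' failed: system {s} leaks emissions "
                f"(relative error {err:.2e})"
            )

    mc_result = None
    if config.mc_yaml:
        spec = _stage("monte_carlo")(load_mc_spec)(config.mc_yaml, config.seed)
        mc_result = _stage("monte_carlo")(results.monte_carlo)(spec)
        mc_result.to_csv(out / "mc_iterates.csv")

    doc = _stage("report")(build_report)(config, results, mc_result)

    results.animals.to_csv(out / "animals.csv", index=False)
    results.system_breakdown().to_csv(out / "system_breakdown.csv", index=False)
    (out / "report.json").write_text(doc.model_dump_json(indent=2) + "\n")
    (out / "report.txt").write_text(_report_text(doc, results))
    (out / "manifest.json").write_text(
        json.dumps(doc.manifest.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    paths = {
        "animals": str(out / "animals.csv"),
        "system_breakdown": str(out / "system_breakdown.csv"),
        "report_json": str(out / "report.json"),
        "report_txt": str(out / "report.txt"),
        "manifest": str(out / "manifest.json"),
    }
    if mc_result is not None:
        paths["mc_iterates"] = str(out / "mc_iterates.csv")
    return paths
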