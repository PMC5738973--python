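"""Representative-animal recomputation, aggregation bias, Monte Carlo
uncertainty and statistical interpretation.

Emissions intensity is a convex (hyperbolic) function of liveweight gain, so
the mean of per-animal intensities always sits at or above the intensity of
a herd-averaged "representative" animal (Jensen's inequality). This module
quantifies that gap — the downward bias a pre-averaged assessment incurs —
alongside the classical Monte Carlo treatment of parameter uncertainty, and
runs the interpretation statistics (one-way ANOVA across systems, pairwise
Welch t-tests, Pearson correlations of intensity against daily gain, and
sex contrasts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tier2 import AnimalRecord, WeighingEvent

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Herd summaries and the representative animal.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HerdSummary:
    """Yearly herd-mean performance variables (the low-resolution statistics
    a pre-averaged assessment would start from).

    Note: the mean ADG is a mean of per-animal ratios, so it only
    approximately equals ``total_growth / days_on_platform`` (ratio of means
    differs from mean of ratios); the representative trajectory is built
    from ``adg`` and ``days_on_platform``, which take precedence.
    """

    farmlet_id: str
    entry_weight: float
    finishing_weight: float
    total_growth: float
    days_on_platform: float
    adg: float

    @classmethod
    def from_herd(cls, herd: Sequence[AnimalRecord]) -> "HerdSummary":
        return cls(
            farmlet_id=herd[0].farmlet_id,
            entry_weight=float(np.mean([a.entry_weight for a in herd])),
            finishing_weight=float(np.mean([a.exit_weight for a in herd])),
            total_growth=float(np.mean([a.lwg for a in herd])),
            days_on_platform=float(np.mean([a.days_on_platform for a in herd])),
            adg=float(np.mean([a.adg for a in herd])),
        )


def representative_animal(
    summary: HerdSummary,
    entry_date: date = date(2014, 10, 15),
    housing_windows: Sequence[tuple[date, date]] = (
        (date(2014, 10, 1), date(2015, 4, 30)),
        (date(2015, 10, 1), date(2016, 4, 30)),
    ),
    weighing_interval: int = 21,
    sex: str = "steer",
) -> AnimalRecord:
    """One synthetic animal growing at the yearly-mean constant rate for the
    yearly-mean duration, weighed on a regular schedule."""
    days = int(round(summary.days_on_platform))
    schedule = list(range(0, days, weighing_interval)) + [days]

    def loc(d: date) -> str:
        return (
            "housing"
            if any(a <= d <= b for a, b in housing_windows)
            else "pasture"
        )

    events = tuple(
        WeighingEvent(
            entry_date + timedelta(days=t),
            summary.entry_weight + summary.adg * t,
            loc(entry_date + timedelta(days=t)),
        )
        for t in schedule
    )
    return AnimalRecord(f"{summary.farmlet_id}-representative",
                        summary.farmlet_id, sex, events)


def aggregation_bias(
    individual_eis: Sequence[float], representative_ei: float
) -> float:
    """Mean per-animal intensity minus the pre-averaged intensity."""
    if len(individual_eis) == 0:
        raise ValueError("need at least one individual emissions intensity")
    return float(np.mean(individual_eis)) - representative_ei


def percent_spread(best_ei: float, worst_ei: float) -> float:
    """Best-to-worst animal spread, (worst - best)/best * 100."""
    if best_ei <= 0:
        raise ValueError("best_ei must be > 0")
    return (worst_ei - best_ei) / best_ei * 100.0


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty.
# ---------------------------------------------------------------------------

_DIST_KINDS = ("normal", "lognormal", "uniform")


@dataclass(frozen=True)
class Distribution:
    """One parameter's sampling distribution.

    ``normal``: N(center, spread); ``lognormal``: center * exp(N(0, ln
    spread)) with spread the geometric SD (>= 1, 1 = degenerate);
    ``uniform``: U(center - spread, center + spread).
    """

    kind: str
    center: float
    spread: float

    def __post_init__(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ValueError(f"kind must be one of {_DIST_KINDS}")
        if self.kind == "lognormal":
            if self.center <= 0 or self.spread < 1.0:
                raise ValueError(
                    "lognormal needs center > 0 and geometric sd >= 1"
                )
        elif self.spread < 0:
            raise ValueError("spread must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "normal":
            return float(rng.normal(self.center, self.spread))
        if self.kind == "lognormal":
            sigma = np.log(self.spread)
            return float(self.center * np.exp(rng.normal(0.0, sigma)))
        return float(rng.uniform(self.center - self.spread,
                                 self.center + self.spread))


@dataclass(frozen=True)
class MCSpec:
    """Monte Carlo recipe: iteration count, seed, and the named parameter
    distributions to draw each iteration."""

    distributions: Mapping[str, Distribution]
    n_iterations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not all(isinstance(d, Distribution)
                   for d in self.distributions.values()):
            raise ValueError("every entry must be a Distribution")


@dataclass
class MCResult:
    """All Monte Carlo iterates plus interval and pairwise summaries."""

    iterates: pd.DataFrame  # columns: iteration, system, ei

    @property
    def systems(self) -> list[str]:
        return sorted(self.iterates["system"].unique())

    def values(self, system: str) -> np.ndarray:
        sel = self.iterates.loc[self.iterates["system"] == system, "ei"]
        return sel.to_numpy()

    def interval(self, system: str, lo: float = 2.5, hi: float = 97.5
                 ) -> tuple[float, float]:
        v = self.values(system)
        return float(np.percentile(v, lo)), float(np.percentile(v, hi))

    def median(self, system: str) -> float:
        return float(np.median(self.values(system)))

    def exceedance(self, a: str, b: str) -> tuple[float, float]:
        """Fraction of iterations with EI_a > EI_b and the two-sided
        exceedance p-value 2*min(f, 1-f)."""
        fa = float(np.mean(self.values(a) > self.values(b)))
        return fa, 2.0 * min(fa, 1.0 - fa)

    def to_csv(self, path) -> None:
        self.iterates.to_csv(path, index=False)


def monte_carlo(
    model_fn: Callable[[Mapping[str, float]], Mapping[str, float]],
    spec: MCSpec,
) -> MCResult:
    """Propagate parameter distributions through a system model.

    ``model_fn`` maps a dict of parameter overrides to per-system emissions
    intensities; it is called once per iteration with freshly drawn values.
    Seeded and reproducible.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for it in range(spec.n_iterations):
        overrides = {name: d.draw(rng) for name, d in spec.distributions.items()}
        for system, ei in model_fn(overrides).items():
            rows.append((it, system, float(ei)))
    return MCResult(pd.DataFrame(rows, columns=["iteration", "system", "ei"]))


# ---------------------------------------------------------------------------
# Statistical interpretation.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    pvalue: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "pvalue": self.pvalue}


@dataclass
class ComparisonReport:
    """Per-system summaries plus the interpretation statistics."""

    per_system: dict[str, dict] = field(default_factory=dict)
    anova: dict[str, TestOutcome] = field(default_factory=dict)
    pairwise_ei: dict[tuple[str, str], TestOutcome] = field(default_factory=dict)
    correlations: dict[str, TestOutcome] = field(default_factory=dict)
    sex_contrasts: dict[str, dict[str, dict]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_system": self.per_system,
            "anova": {k: v.to_dict() for k, v in self.anova.items()},
            "pairwise_ei": {
                f"{a}_vs_{b}": v.to_dict() for (a, b), v in self.pairwise_ei.items()
            },
            "correlations": {k: v.to_dict() for k, v in self.correlations.items()},
            "sex_contrasts": self.sex_contrasts,
            "warnings": list(self.warnings),
        }


def _usable_groups(groups: Sequence[np.ndarray]) -> bool:
    return (
        len(groups) >= 2
        and all(len(g) >= 2 for g in groups)
        and any(np.std(g) > 0 for g in groups)
    )


def interpret(
    animals: pd.DataFrame, equal_var: bool = False
) -> ComparisonReport:
    """Interpretation statistics over a per-animal results frame.

    ``animals`` needs columns: system, animal_id, sex, adg, lwg, days, ei.
    Welch's unequal-variance t-test is the default pairwise test; set
    ``equal_var=True`` for the exact Student variant. Degenerate groups
    (n < 2 or zero variance everywhere) skip their test with a warning.
    """
    report = ComparisonReport()
    systems = sorted(animals["system"].unique())

    for system in systems:
        grp = animals[animals["system"] == system]
        report.per_system[system] = {
            "n": int(len(grp)),
            "mean_ei": float(grp["ei"].mean()),
            "best_ei": float(grp["ei"].min()),
            "worst_ei": float(grp["ei"].max()),
            "percent_spread": percent_spread(
                float(grp["ei"].min()), float(grp["ei"].max())
            ),
            "mean_adg": float(grp["adg"].mean()),
        }

    for var in ("ei", "adg"):
        groups = [
            animals.loc[animals["system"] == s, var].to_numpy() for s in systems
        ]
        if _usable_groups(groups):
            f, p = stats.f_oneway(*groups)
            report.anova[var] = TestOutcome(float(f), float(p))
        else:
            report.warnings.append(f"ANOVA on {var} skipped: degenerate groups")

    for i, a in enumerate(systems):
        for b in systems[i + 1:]:
            ga = animals.loc[animals["system"] == a, "ei"].to_numpy()
            gb = animals.loc[animals["system"] == b, "ei"].to_numpy()
            if _usable_groups([ga, gb]):
                t, p = stats.ttest_ind(ga, gb, equal_var=equal_var)
                report.pairwise_ei[(a, b)] = TestOutcome(float(t), float(p))
            else:
                report.warnings.append(
                    f"t-test {a} vs {b} skipped: degenerate groups"
                )

    for system in systems:
        grp = animals[animals["system"] == system]
        if len(grp) >= 3 and grp["adg"].std() > 0 and grp["ei"].std() > 0:
            r, p = stats.pearsonr(grp["ei"], grp["adg"])
            report.correlations[system] = TestOutcome(float(r), float(p))
        else:
            report.warnings.append(
                f"correlation for {system} skipped: degenerate data"
            )

    for system in systems:
        grp = animals[animals["system"] == system]
        steers = grp[grp["sex"] == "steer"]
        heifers = grp[grp["sex"] == "heifer"]
        contrasts: dict[str, dict] = {}
        for var in ("ei", "lwg", "days"):
            gs, gh = steers[var].to_numpy(), heifers[var].to_numpy()
            if _usable_groups([gs, gh]):
                t, p = stats.ttest_ind(gs, gh, equal_var=equal_var)
                contrasts[var] = {
                    "mean_steer": float(np.mean(gs)),
                    "mean_heifer": float(np.mean(gh)),
                    "difference": float(np.mean(gs) - np.mean(gh)),
                    "statistic": float(t),
                    "pvalue": float(p),
                }
            else:
                report.warnings.append(
                    f"sex contrast on {var} for {system} skipped"
                )
        report.sex_contrasts[system] = contrasts

    if report.warnings:
        for w in report.warnings:
            logger.warning(w)
    return report
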