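"""Distribution summaries and the validated output-report schema.

Five-number summaries use linear-interpolation (type-7) quartiles so the
1.5 x IQR outlier flags are reproducible across environments. The JSON
report written by the pipeline is validated against pydantic models whose
generated JSON schema is committed at ``schema/report.schema.json``.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field


def five_number_summary(values) -> dict:
    """Min, Q1, median, Q3, max plus 1.5 x IQR whiskers and outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = (float(np.percentile(v, q)) for q in (25, 50, 75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "q1": q1,
        "median": med,
        "q3": q3,
        "max": float(v.max()),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in sorted(outliers)],
    }


def summarize_distributions(animals: pd.DataFrame) -> dict:
    """Per-system and per-system/sex five-number EI summaries.

    ``animals`` needs columns system, sex, ei (the per-animal results frame).
    """
    out: dict = {}
    for system, grp in animals.groupby("system"):
        entry = {"all": five_number_summary(grp["ei"])}
        for sex, sub in grp.groupby("sex"):
            entry[str(sex)] = five_number_summary(sub["ei"])
        out[str(system)] = entry
    return out


# ---------------------------------------------------------------------------
# Report schema (pydantic).
# ---------------------------------------------------------------------------

class TestStat(BaseModel):
    statistic: float
    pvalue: float


class SystemSummary(BaseModel):
    n: int
    mean_ei: float
    best_ei: float
    worst_ei: float
    percent_spread: float
    mean_adg: float


class RepresentativeEntry(BaseModel):
    mean_individual_ei: float
    representative_ei: float
    bias: float


class MCSystemEntry(BaseModel):
    median: float
    p2_5: float
    p97_5: float


class Manifest(BaseModel):
    package: str = "herdlca"
    version: str
    seed: Optional[int] = None
    config_hash: str
    gwp: str
    allocation: str
    cattle_share: float


class ReportDocument(BaseModel):
    """Top-level pipeline report."""

    manifest: Manifest
    per_system: Mapping[str, SystemSummary]
    representative: Mapping[str, RepresentativeEntry]
    anova: Mapping[str, TestStat] = Field(default_factory=dict)
    pairwise_ei: Mapping[str, TestStat] = Field(default_factory=dict)
    correlations: Mapping[str, TestStat] = Field(default_factory=dict)
    sex_contrasts: Mapping[str, Mapping[str, Mapping[str, float]]] = Field(
        default_factory=dict
    )
    distributions: Mapping[str, Mapping[str, dict]] = Field(default_factory=dict)
    monte_carlo: Optional[Mapping[str, MCSystemEntry]] = None
    mc_pairwise: Optional[Mapping[str, TestStat]] = None
    warnings: list[str] = Field(default_factory=list)


def config_hash(config: Mapping) -> str:
    """Deterministic hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_schema(path) -> None:
    """Emit the JSON schema the pipeline's report conforms to."""
    with open(path, "w") as fh:
        json.dump(ReportDocument.model_json_schema(), fh, indent=2, sort_keys=True)
        fh.write("\n")
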