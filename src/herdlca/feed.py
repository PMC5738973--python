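"""Feed-quality conversions and time-resolved quality lookup.

Laboratory forage measurements arrive as modified acid detergent fibre
(MADF, g/kg DM) and total nitrogen (% DM). The Tier 2 engine consumes
digestible energy (DE, % of gross energy) and crude protein (CP, % DM). This
module performs the conversions

    ME  = a + b * MADF          (affine, per feed type; b < 0)
    DE  = c + d * ME            (via the digestible-organic-matter relation)
    CP  = 6.25 * N

and serves the quality in force for any animal-period via last-observation-
carried-forward interpolation of the dated sample series.

The MADF->ME and ME->DE calibration coefficients are not universal constants;
the defaults shipped here are assumed, editable values chosen so that typical
UK pasture and silage fibre levels map into realistic DE bands. Override them
through the ``feed_conversion`` config block for any serious application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

PASTURE = "pasture"
SILAGE = "silage"
FEED_TYPES = (PASTURE, SILAGE)


class CalibrationError(ValueError):
    """A conversion left its physically meaningful range."""


@dataclass(frozen=True)
class ConversionCoefficients:
    """Coefficients of the affine feed-quality conversions.

    ``me_from_madf`` maps feed type -> (intercept MJ/kg DM, slope MJ/kg DM per
    g/kg MADF, slope <= 0); ``de_from_me`` is (intercept %, slope % per MJ,
    slope > 0); ``cp_from_n`` is the protein-to-nitrogen ratio.
    """

    me_from_madf: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # assumed, editable: calibrated to map MADF ~250 (pasture) and
            # ~300 g/kg (silage) into the DE bands typical of each feed.
            PASTURE: (17.30, -0.0205),
            SILAGE: (16.50, -0.0210),
        }
    )
    de_from_me: tuple[float, float] = (0.0, 1.0 / 0.157)  # DOMD relation
    cp_from_n: float = 6.25

    def __post_init__(self) -> None:
        if self.cp_from_n <= 0:
            raise ValueError("cp_from_n must be positive")
        for ft, (_, slope) in self.me_from_madf.items():
            if slope > 0:
                raise ValueError(
                    f"ME-vs-MADF slope must be <= 0 (more fibre, less energy); "
                    f"got {slope} for {ft!r}"
                )
        if self.de_from_me[1] <= 0:
            raise ValueError("DE must increase with ME")


@dataclass(frozen=True)
class FeedSample:
    """One dated laboratory sample; raw (madf/total_n) and/or converted
    (de_pct/cp_pct) fields."""

    farmlet_id: str
    feed_type: str
    date: date
    madf: Optional[float] = None
    total_n: Optional[float] = None
    de_pct: Optional[float] = None
    cp_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.feed_type not in FEED_TYPES:
            raise ValueError(f"feed_type must be one of {FEED_TYPES}")
        if self.madf is None and self.de_pct is None:
            raise ValueError("sample needs madf or de_pct")
        if self.total_n is None and self.cp_pct is None:
            raise ValueError("sample needs total_n or cp_pct")
        for name in ("madf", "total_n", "de_pct", "cp_pct"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("de_pct", "cp_pct"):
            v = getattr(self, name)
            if v is not None and v >= 100:
                raise ValueError(f"{name} must be < 100")


def madf_to_me(madf: float, feed_type: str, coeffs: ConversionCoefficients) -> float:
    """Metabolisable energy (MJ/kg DM) from fibre content."""
    if madf < 0:
        raise ValueError("madf must be >= 0")
    try:
        intercept, slope = coeffs.me_from_madf[feed_type]
    except KeyError:
        raise CalibrationError(f"no MADF->ME coefficients for {feed_type!r}")
    me = intercept + slope * madf
    if me <= 0:
        raise CalibrationError(
            f"MADF {madf} g/kg ({feed_type}) maps to non-positive ME {me:.3f}"
        )
    return me


def me_to_de(me: float, coeffs: ConversionCoefficients) -> float:
    """Digestible energy (% of gross energy) from metabolisable energy."""
    if me <= 0:
        raise ValueError("me must be > 0")
    c, d = coeffs.de_from_me
    de = c + d * me
    if not 0.0 < de < 100.0:
        raise CalibrationError(f"ME {me} MJ/kg maps to DE {de:.2f}% outside (0, 100)")
    return de


def n_to_cp(total_n: float, coeffs: ConversionCoefficients) -> float:
    """Crude protein (% DM) from total nitrogen (% DM)."""
    if total_n < 0:
        raise ValueError("total_n must be >= 0")
    return coeffs.cp_from_n * total_n


def convert_sample(
    sample: FeedSample, coeffs: ConversionCoefficients
) -> tuple[float, float]:
    """Resolve a sample to (DE %, CP %). Converted fields win over raw ones;
    the clash is logged because measured values beat modelled ones."""
    if sample.de_pct is not None:
        if sample.madf is not None:
            logger.warning(
                "sample %s/%s %s carries both madf and de_pct; using de_pct",
                sample.farmlet_id, sample.feed_type, sample.date,
            )
        de = sample.de_pct
    else:
        de = me_to_de(madf_to_me(sample.madf, sample.feed_type, coeffs), coeffs)
    if sample.cp_pct is not None:
        if sample.total_n is not None:
            logger.warning(
                "sample %s/%s %s carries both total_n and cp_pct; using cp_pct",
                sample.farmlet_id, sample.feed_type, sample.date,
            )
        cp = sample.cp_pct
    else:
        cp = n_to_cp(sample.total_n, coeffs)
    return de, cp


class FeedQualitySeries:
    """Dated DE/CP values per (farmlet, feed type), with period averaging.

    The series is a step function: each sample's value holds from its date
    until the next sample; dates before the first sample fall back to the
    first sample (the least-assumptive reading of sparse sampling).
    """

    COLUMNS = ("farmlet", "feed_type", "date", "de_pct", "cp_pct")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"feed series missing columns: {sorted(missing)}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df = df.sort_values(["farmlet", "feed_type", "date"]).reset_index(drop=True)
        if ((df["de_pct"] <= 0) | (df["de_pct"] >= 100)).any():
            raise ValueError("de_pct must lie in (0, 100)")
        if ((df["cp_pct"] < 0) | (df["cp_pct"] >= 100)).any():
            raise ValueError("cp_pct must lie in [0, 100)")
        self._df = df

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_samples(
        cls,
        samples: Iterable[FeedSample],
        coeffs: ConversionCoefficients | None = None,
    ) -> "FeedQualitySeries":
        coeffs = coeffs or ConversionCoefficients()
        rows = []
        for s in samples:
            de, cp = convert_sample(s, coeffs)
            rows.append((s.farmlet_id, s.feed_type, s.date, de, cp))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "FeedQualitySeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def shifted(self, de_offset: float = 0.0, cp_offset: float = 0.0
                ) -> "FeedQualitySeries":
        """Copy with DE/CP shifted by constants (clipped to stay in range);
        used by uncertainty propagation."""
        df = self._df.copy()
        df["de_pct"] = (df["de_pct"] + de_offset).clip(0.1, 99.9)
        df["cp_pct"] = (df["cp_pct"] + cp_offset).clip(0.0, 99.9)
        return FeedQualitySeries(df)

    # -- lookup -------------------------------------------------------------
    def _steps(self, farmlet: str, feed_type: str) -> pd.DataFrame:
        sel = self._df[
            (self._df["farmlet"] == farmlet) & (self._df["feed_type"] == feed_type)
        ]
        if sel.empty:
            raise KeyError(
                f"no feed samples for farmlet={farmlet!r}, feed_type={feed_type!r}"
            )
        return sel

    def value_on(self, farmlet: str, feed_type: str, day: date
                 ) -> tuple[float, float]:
        """DE/CP in force on a single day (LOCF; first sample before start)."""
        steps = self._steps(farmlet, feed_type)
        prior = steps[steps["date"] <= day]
        row = prior.iloc[-1] if not prior.empty else steps.iloc[0]
        return float(row["de_pct"]), float(row["cp_pct"])

    def quality_at(
        self, farmlet: str, feed_type: str, start: date, end: date
    ) -> tuple[float, float]:
        """Time-weighted mean (DE %, CP %) over the half-open period
        [start, end)."""
        if end <= start:
            raise ValueError("period must satisfy start < end")
        steps = self._steps(farmlet, feed_type)
        dates = list(steps["date"])
        de = list(steps["de_pct"])
        cp = list(steps["cp_pct"])
        # Breakpoints: period start, then every sample date inside the period.
        cuts = [start] + [d for d in dates if start < d < end] + [end]
        total_days = (end - start).days
        wde = wcp = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            # value in force on [a, b): last sample with date <= a, else first
            idx = None
            for i, d in enumerate(dates):
                if d <= a:
                    idx = i
                else:
                    break
            if idx is None:
                idx = 0
            w = (b - a).days
            wde += de[idx] * w
            wcp += cp[idx] * w
        return wde / total_days, wcp / total_days

    def yearly_mean(self, farmlet: str, feed_type: str) -> tuple[float, float]:
        """Unweighted mean DE/CP across all samples of one series (the
        low-resolution quality a pre-averaged assessment would use)."""
        steps = self._steps(farmlet, feed_type)
        return float(steps["de_pct"].mean()), float(steps["cp_pct"].mean())
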