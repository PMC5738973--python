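# Methods

This document describes the model implemented by `herdlca`: its equations,
parameter defaults, the synthetic data generators, numerical choices and
known limitations. Units are kg, MJ, days and kg CO2-equivalent unless
stated otherwise.

## 1. Scope and system boundary

The functional unit is 1 kg of liveweight gain (LWG) during the finishing
stage: animals enter the farm platform at a recorded weight and leave at
slaughter-ready weight. The boundary is cradle-to-farm-gate for the
finishing stage only — cow-calf emissions before arrival are excluded, as
are slaughter and processing. Included are:

- enteric methane and manure methane from the finishing cattle;
- direct and indirect N2O from managed manure (winter housing on straw
  deep bedding) and from excreta deposited on pasture;
- soil N2O from fertiliser N, applied farmyard manure N, crop residues of
  reseeded leys and the excreta of a co-grazing ewe flock, plus the
  leaching-indirect pathway;
- CO2 from lime and the embedded (upstream) burdens of purchased inputs
  (fertilisers, bedding straw, soybean feed, seeds, agrochemicals, diesel)
  and their transport;
- annualised burdens of periodic pasture reseeding.

Emissions are tracked as gas masses (CH4, N2O, CO2) in per-source ledger
records and only characterized at the end, so GWP sets can be swapped.

## 2. Tier 2 energy and nitrogen engine (`tier2.py`)

Each animal is a sequence of dated weighings with a location (pasture or
housing). Consecutive weighings bound half-open periods `[start, end)`;
each period gets the feed quality of its location (pasture herbage or grass
silage when housed) averaged over its days from the dated feed series.

Per period, with mean weight `W`, period daily gain `ADG` and feed
digestibility `DE` (% of gross energy):

- maintenance: `NEm = Cfi * W^0.75`, `Cfi = 0.322` (castrate/heifer);
- activity: `NEa = Ca * NEm`, `Ca = 0.17` grazing, `0` housed;
- growth: `NEg = 22.02 * (W / (C * MW))^0.75 * ADG^1.097` with `C = 1.0`
  for steers, `0.8` for heifers and mature weights 620/555 kg; `NEg = 0`
  when `ADG <= 0`;
- `REM = 1.123 - 4.092e-3*DE + 1.126e-5*DE^2 - 25.4/DE` and
  `REG = 1.164 - 5.160e-3*DE + 1.308e-5*DE^2 - 37.4/DE`;
- gross energy `GE = [(NEm + NEa)/REM + NEg/REG] / (DE/100)` (MJ/day).

Methane and nitrogen flows:

- enteric CH4 = `GE * days * (Ym/100) / 55.65`, `Ym = 6.5%` everywhere,
  55.65 MJ/kg CH4 (fixed by validation — it is a physical constant);
- volatile solids `VS/day = [GE*(1 - DE/100) + UE*GE] * (1 - ASH)/18.45`
  with urinary energy fraction `UE = 0.04` and ash `0.08`;
- manure CH4 = `VS * days * B0 * 0.67 * MCF/100`, `B0 = 0.18` m3 CH4/kg VS,
  `MCF = 20%` for deep bedding (housed), `1%` for pasture deposition;
- N intake/day = `(GE/18.45) * (CP/100) / 6.25`; N retained/day =
  `ADG * (268 - 7.03 * NEg/ADG) / 1000 / 6.25`, floored at 0 for
  non-growing periods; N excreted = intake − retention;
- N2O-N: housed N × `EF3 = 0.01` (direct) and × volatilisation fraction
  `0.30` × `EF4 = 0.01` (indirect); grazed N × `EF3,PRP = 0.02` plus
  leaching fraction `0.30` × `EF5 = 0.0075`. N2O-N → N2O by 44/28.

All parameters live in a frozen `ParameterSet` whose every field carries a
provenance string ("IPCC 2006 default", "assumed", …); `replace()` marks
changed values "assumed", and YAML round trips preserve provenance.

## 3. Feed quality (`feed.py`)

Laboratory measurements arrive either directly as DE%/CP% or as modified
acid detergent fibre (MADF) and total N. Conversions:

- `ME = a - b*MADF` (MJ/kg DM): pasture `17.30 - 0.0205*MADF`, silage
  `16.50 - 0.0210*MADF` (standard UK forage regressions; assumed);
- `DE% = ME / 0.157` (the ME ≈ 0.82·DE with 18.45 MJ/kg GE convention);
- `CP = 6.25 * N` exactly.

Out-of-range results (non-positive ME, DE outside (0, 100)) raise a
calibration error rather than propagating nonsense. When both measured and
convertible inputs exist, the measured value wins with a logged warning.
The dated series interpolates last-observation-carried-forward in time and
averages day-weighted over each animal period.

## 4. Farmlet pool and allocation (`upstream.py`, `allocation.py`)

Field and purchased-input burdens cannot be attributed to an individual at
source, so they enter a per-farmlet pool. Soil N2O uses `EF1 = 0.01` on
fertiliser, FYM (6 kg N/t fresh, assumed), crop-residue and sheep-excreta
N, plus the leaching pathway. Upstream factors (kg CO2-eq per unit) are
**assumed placeholder magnitudes** shipped with "assumed" provenance — e.g.
8.9/kg N ammonium nitrate, 0.55/kg lime, 3.2/l diesel, 0.011/t-km sea and
0.11/t-km road freight — and should be replaced with database values for a
real assessment. Reseeded systems annualise one renewal's diesel and
glyphosate over a five-year sowing interval; permanent pasture gets none.

The cattle platform is co-grazed by a ewe flock, so pool burdens and the
pasture-deposition burdens of cattle excreta are shared between enterprises:
economic allocation 78/22 cattle/sheep (default) or feed-mass 72/28. The
cattle share of the pool is split evenly across the herd (1/n each);
enteric and housed-manure emissions stay with their animal in full. Sheep
deductions are kept as explicit records so that per-gas mass is conserved:
the suite asserts Σ per-animal + sheep = system total at 1e-9 relative
(achieved at ~1e-16).

Characterization uses GWP100 factor sets AR5 (CH4 28, N2O 265) and AR4
(25, 298), CO2 ≡ 1. Emissions intensity is allocated CO2-eq divided by the
animal's LWG; animals with non-positive LWG are excluded from the EI
distribution (with a logged warning) but still count in system totals.

## 5. Synthetic herd generator (`synthetic.py`)

The generator emulates what a finishing trial's weighing database looks
like; it is calibrated to reproduce published *summary statistics* (herd
mean and SD of whole-record ADG, entry weights), not any real animal.

Each animal draws an entry weight and a base ADG, then walks a weighing
schedule (uniform 14–28 day intervals) until its first weighing at or above
the sex target (620 kg steers, 555 kg heifers; capped at 1500 days).
Period gains follow a three-phase growth shape — a slow post-arrival dip,
a strong second-season peak and a finishing plateau, piecewise-linear over
day knots (0, 90, 270, 480) — normalised per animal over its expected
horizon, plus N(0, 0.15) kg/d period noise (gut fill, scale error). Steers
carry a 0.10 kg/d mean ADG advantage; the between-sex variance is carved
out of the herd SD and the gap is clamped so the herd-level mean and SD
contracts are preserved at any sex ratio.

The stopping rule, curve normalisation and period noise all distort the
realised whole-record ADG moments away from the base-draw moments, so the
generator **self-calibrates**: it simulates a 3000-animal pilot of its own
stopping process under a fixed internal seed, measures the realised
mean/SD, and corrects the base draw (two additive steps, cached per spec
family). The suite verifies realised moments at n = 3000 against the
requested ones for all three study systems.

Feed series are seasonal cosines (peak quality in mid-May) around the
published annual DE/CP means with assumed spreads, sampled every 21 days.
Published summary tables (inventory, performance, per-source contribution)
ship as packaged CSV fixtures and seed the study defaults, including
assumed N depositions the tables do not print (1800 kg/yr ewe excretal N;
150 kg/yr residue N on reseeded systems).

## 6. Representative animal, bias, Monte Carlo, statistics (`compare.py`)

The representative animal grows linearly at the herd-mean ADG from the
herd-mean entry weight for the herd-mean duration, weighed every 21 days,
and is evaluated with yearly-mean feed quality; the pool is still divided
by the full herd size n. Aggregation bias = mean individual EI −
representative EI. For an animal-invariant burden this is non-negative by
Jensen's inequality (EI is convex in LWG); the suite proves the property
over 200 random herds.

In simulated herds the bias is small (≲0.15 kg CO2-eq/kg LWG) and can be
marginally negative, because in practice burdens are not animal-invariant
and the normal ADG draw rarely produces the near-zero-gain "poor doers"
that drive large biases in real data; the packaged contribution table
arithmetic (printed totals minus representative point estimates, up to
1.7) reflects the real-data case.

Monte Carlo draws named parameter distributions (normal; lognormal as
center × exp(N(0, ln gsd)); uniform) and re-evaluates per-system EI through
a vectorised path (`model._system_totals`, numpy `bincount` over aligned
period arrays) that matches the record-based fit to 1e-9 and runs ~1000
iterations in seconds. Supported names are all Tier 2 parameter fields
plus `feed_de_offset`, `feed_cp_offset` and `upstream_scale`. Outputs are
medians, 95% percentile intervals and paired exceedance probabilities
`2*min(f, 1-f)` computed on common random numbers.

Interpretation statistics: one-way ANOVA across systems, pairwise Welch
t-tests (unequal variance by default), Pearson EI–ADG correlations, and
steer/heifer contrasts. Box summaries use linear-interpolation (type-7)
quartiles with 1.5×IQR whiskers/outliers for cross-platform
reproducibility.

## 7. Numerical and software choices

- All stochastic code uses `numpy.random.Generator` seeded explicitly;
  derived seeds are reduced mod 2^31. Pipeline reruns are byte-identical.
- Periods are half-open `[start, end)`; re-partitioning a constant-weight
  record is exactly additive, while growing records differ only through
  the concavity of `W^0.75` (bounded at ~1e-3 relative, tested).
- Ledger records are frozen dataclasses validated against a 14-source
  registry (source/gas/scope consistency, non-negative finite mass).
- The JSON report is validated by pydantic models; the generated schema is
  committed at `schema/report.schema.json` and compared in the suite.
- Statistics come from scipy (`f_oneway`, `ttest_ind`, `pearsonr`), not
  re-implementations.

## 8. Limitations

- Upstream emission factors, the MADF/ME regressions and several N
  depositions are assumed values, flagged as such in provenance; absolute
  EI levels therefore carry a calibration caveat even though system
  rankings and per-animal spreads are robust to them.
- The Tier 2 equations use period-mean weights; very long inter-weighing
  gaps coarsen the energy balance.
- The sheep enterprise is represented only through its allocation share
  and excretal N; sheep production is not modelled.
- The growth-curve shape and sex gap in the generator are structural
  assumptions chosen for realism, calibrated only to herd-level moments.
- No soil carbon-stock change, land-use change, or cow-calf stage.
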