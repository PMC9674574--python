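# Methods

## The model

`cropcal` implements a climate-driven, rule-based model of farmers' growing
-period decisions for five grain crops (maize, rice, sorghum, soybean,
wheat), the cultivar parameterization consistent with those decisions, and
a daily thermal-time phenology simulator that closes the loop. The premise
is that farmers select sowing dates and cultivars from the mean climatic
character of their location, subject to the crop's physiological limits
(base and optimal temperatures for reproductive growth, sensitivity to
terminal water stress).

### Calendar rules

A cell's 12-month climatology is classified by the coefficient of variation
(sample sd / mean) of monthly temperature (in kelvin) and precipitation.
Exceeding `cv_temp > 0.01` marks temperature seasonality, `cv_prec > 0.4`
precipitation seasonality; both thresholds are configuration, since they are
method conventions rather than measurements. Under precipitation
seasonality, spring crops are sown on the first day of the wettest 120
consecutive days; under temperature seasonality, on the day daily
temperature first rises above the crop's sowing threshold. Cells seasonal in
both use temperature rules when the coldest month is below the crop's
sowing threshold (winter limits growth there) and precipitation rules
otherwise. Aseasonal cells sow on a fixed default day (DOY 1 north / 182
south).

Wheat resolves into three types from the winter character: *winter wheat
with vernalization* needs a real winter (a month below 0 °C) that is
neither too harsh (coldest month above −10 °C) nor too long (daily
temperature falls below the 12 °C sowing threshold only after 15 Sep north
/ 31 Mar south) and is sown at that falling crossing; *winter wheat without
vernalization* grows over mild winters (coldest month above 0 °C) and is
sown 75 days before the coldest-month mid-day; otherwise *spring wheat*
follows the spring-crop rules.

Maturity places grain filling — 60 days for maize, 40 for the others — in
the least stressful window: spring crops start grain filling at the
warmest-month mid-day (or when temperature falls back inside the optimal
range); winter wheat *ends* grain filling at the warmest-month mid-day, or
on the day temperature first exceeds 25 °C; precipitation-driven cells
start grain filling when daily P/PET drops below the crop threshold after
the wet-season midpoint. Maturity is advanced to a P/PET collapse during
grain filling (terminal water stress) provided grain filling keeps at least
10 days and the season its 90-day minimum; the full season is clamped to
[90, 330] days. All dates use a 1-based, 365-day no-leap calendar with
circular arithmetic; daily series are piecewise-linear interpolations of
monthly values between mid-month anchors, wrapping December to January.
Ties (equal windows, runs at a threshold, equal extreme months) always
resolve to the earliest index.

### Cultivars

A locally adapted cultivar is the pair (TU_req, VU_req). TU_req accumulates
daily mean temperature above the crop base temperature between the
rule-based sowing and maturity dates, scaled by vernalization progress for
vernalizing winter wheat. VU_req (0–70 effective vernalization days) is set
by the five coldest months: each contributes 14 · (1 − (T_m − 3)/7),
clamped to [0, 14]. Daily vernalization effectiveness is trapezoidal: zero
outside (−4, 17) °C, one on [3, 10] °C, linear flanks of width 7 °C. The
TU multiplier is held at 1 until 10% of VU_req is accumulated (allowing
fall leaf growth), then equals the raw progress fraction capped at 1; the
"raw vs rescaled progress" choice is open in the method's description and
raw was chosen for simplicity.

### Phenology simulation and yield index

The forward simulator runs the same accumulation from sowing under
arbitrary daily weather: maturity is the first day TU ≥ TU_req (within a
365-day default horizon; non-maturation is an outcome, not an error). The
harvest-index curve fHI = 100·fTU/(100·fTU + e^(11.1 − 10·fTU)) ties yield
formation to thermal progress; a flowering proxy fires at 45% (wheat) or
50% (others) of TU_req; a daily minimum below −5 °C while 0.5 < fTU < 0.95
fails the crop. Calibration and simulation share one increment routine and
a sequential cumulative sum, so simulating on the calibration climatology
reproduces the rule-based maturity date exactly (the round-trip tests
require ±1 day).

The yield quantity is deliberately a **toy index**: summed daily
temperature suitability (trapezoid from the base temperature through the
optimal grain-filling range, back to zero 10 °C above it) over the realized
season, times final fHI, zeroed on frost failure or non-maturation. Its
only contracts are determinism and monotone response to season suitability.
It is not a biophysical growth model: scenario results support sign and
ordering statements only, never magnitude claims.

## Adaptation scenarios

The protocol crosses a calibration period against a simulation period:
reference (baseline/baseline), no adaptation (baseline/future), delayed
adaptation (intermediate/future), timely adaptation (future/future), plus
single-measure variants that take only the sowing date or only the cultivar
from the future calibration. Per cell, 20 seeded weather years (climatology
plus AR(1) anomalies, persistence 0.8, sd 1 °C and 0.5 mm/day by default)
drive the simulator; weather is generated on the calendar year and sliced
at each calendar's sowing day, so scenarios sharing a simulation period see
bit-identical weather. Benefits are relative mean-yield differences against
no adaptation; with masking on, non-positive benefits are recorded as zero
and flagged (farmers keep the old practice rather than adopt a losing one).
Aggregation is harvested-area weighted; yield variability is the
coefficient of variation with sample (n−1) sd.

## Synthetic climate

The generator emulates the climate structures the rules branch on:
sinusoidal annual temperature cycles (extratropics), rainfall concentrated
in a circular wet season (tropics), mixed and flat cells; PET is a linear
function of monthly temperature (10 + 4·T mm/month, floored at zero),
which suffices for P/PET threshold logic but is not a physical PET scheme.
Perturbations shift temperature (uniform or month-resolved), scale
precipitation, and move PET along its temperature link. The mixed fixture
grid spans both hemispheres, all four seasonality classes, and the
winter-wheat decision breakpoints, while keeping the warmest month above
~18 °C so every default crop has a workable thermal season. What the
generator does **not** emulate: day-to-day weather from real forcing,
spatial correlation between cells, precipitation intermittency, trends
within a period, or any specific GCM. Tests passing on this climate
demonstrate the rule logic and its internal consistency, not skill against
observed calendars or yields.

## Numerical choices

- 365-day calendar; mid-month anchors at first day + (length − 1)/2;
  monthly precipitation and PET converted to per-day rates before
  interpolation.
- P/PET where PET = 0 is reported as a large sentinel (10^6): rules only
  test "falls below", so zero PET means no water limitation.
- Crossings are events: day d crosses rising iff series[d−1] < θ ≤
  series[d]; a run exactly at the threshold is entered on its first day
  but never "crossed from".
- Degenerate inputs: TU_req = 0 matures on day 1; an all-below-base season
  yields TU_req = 0; a calendar whose clamped grain-filling start leaves
  the growing period raises a rule-failure diagnostic naming the branch.
- Problem sizes in the shipped tests (1000 random cells for oracle
  equivalence, a 200-cell grid for round-trip checks, 8–40 cells × 5–20
  years for scenario machinery) were chosen to exercise every branch while
  keeping the default suite fast.

## Known limitations

Single cycle per year; no multiple cropping or rotations; no photoperiod
response; one base temperature per crop across phases; air (not canopy)
temperature; the yield index has no water balance, CO₂ response, radiation
or allocation, so adaptation *benefit magnitudes* from this package are not
comparable to estimates from full biophysical crop models. Crop parameter
defaults are literature-consistent but uncalibrated; treat them as a
starting point for regional recalibration.
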