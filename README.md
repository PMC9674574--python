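# cropcal

Rule-based selection of crop growing periods from climate, cultivar
thermal-time parameterization, and growing-season adaptation scenarios
under climate change — for maize, rice, sorghum, soybean and wheat.

Farmers pick sowing dates and cultivars to fit the climate they
experience: sowing at the onset of the rainy season in the tropics, at the
spring warming threshold in the extratropics, in fall for winter wheat;
and choosing maturity classes so that grain filling lands in the least
stressful part of the year. `cropcal` encodes these decision rules,
derives the cultivar parameters consistent with them, and asks what
happens to growing periods and (index-level) yields when the climate the
rules are calibrated on and the climate the crop experiences diverge —
the no/delayed/timely adaptation question.

The package is aimed at crop-modelling and agro-climate researchers who
want the decision layer — calendars, cultivars, adaptation protocol —
separate from any particular biophysical growth model, exercisable
end-to-end on synthetic climate.

## The model in brief

- **Sowing.** Precipitation-seasonal cells sow on the first day of the
  wettest 120 consecutive days; temperature-seasonal cells at the rising
  crossing of a crop-specific threshold. Wheat resolves into winter (with
  or without vernalization) or spring types from the coldest-month
  temperature (breakpoints 0 °C and −10 °C) and the timing of fall
  cooling (after 15 Sep N / 31 Mar S); winter wheat without vernalization
  is sown 75 days before the coldest month.
- **Maturity.** Grain filling (60 days maize, 40 otherwise) starts at the
  warmest-month mid-day for spring crops (or once temperatures return to
  the optimal range), ends there for winter wheat (or on the day the
  25 °C terminal-heat threshold is crossed), and starts at the P/PET
  collapse after the wet season in precipitation-driven cells; terminal
  water stress advances maturity.
- **Cultivars.** TU_req = Σ max(0, T_d − T_base) × v_d between sowing and
  maturity, where v_d is the vernalization progress multiplier (held at 1
  until 10% of VU_req, then the progress fraction). VU_req ∈ [0, 70]
  effective vernalization days from the five coldest months, 14·(1 −
  (T_m − 3)/7) each, clamped to [0, 14].
- **Phenology & yield index.** A daily simulator accumulates the same
  quantities under arbitrary weather; maturity when TU_req is met; harvest
  index fHI = 100·fTU/(100·fTU + e^(11.1−10·fTU)); frost failure below
  −5 °C during 0.5 < fTU < 0.95. Yield is a deliberately simple
  suitability×fHI index for scenario ordering, not a biophysical model.
- **Scenarios.** Calibrate calendars+cultivars on one climate period,
  simulate on another (reference / no / delayed / timely adaptation, plus
  sowing-only and cultivar-only), with area-weighted aggregation,
  adaptation benefits, and yield CV over 20 seeded weather years.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
from cropcal import (build_calendar, default_crop_params,
                     interpolate_monthly_to_daily, tu_req_from_calendar,
                     gen_monthly_climatology, preset)

params = default_crop_params()
mc = gen_monthly_climatology(preset("temperate"))   # mid-latitude cell
dc = interpolate_monthly_to_daily(mc)

for crop in ("maize", "wheat"):
    cal = build_calendar(mc, params[crop], "N", dc=dc)
    cv = tu_req_from_calendar(dc, cal, params[crop], mc=mc)
    print(f"{crop:6s} sow={cal.sowing_doy} gf={cal.gf_start_doy} "
          f"mat={cal.maturity_doy} "
          f"type={cal.wheat_type.value if cal.wheat_type else '-'} "
          f"TU_req={cv.tu_req:.1f} VU_req={cv.vu_req:.1f}")
```

prints

```
maize  sow=134 gf=197 mat=257 type=- TU_req=1579.5 VU_req=0.0
wheat  sow=272 gf=157 mat=197 type=WINTER_VERN TU_req=1892.2 VU_req=68.4
```

Maize is sown on DOY 134 (mid-May), when daily temperature first exceeds
14 °C; grain filling starts at the warmest-month mid-day (DOY 197,
mid-July) and runs 60 days to maturity on DOY 257. The cell's winter is
cold but mild enough for vernalizing winter wheat: sown DOY 272 (late
September) as temperatures fall through 12 °C, maturing at the July
mid-day, with a near-maximal vernalization requirement (68.4 of 70 days)
and 1892 °C·day of thermal units.

The same pipeline from the shell:

```sh
cropcal synth --preset mixed-grid --n-cells 6 --seed 1 --out clim.csv
cropcal calendar --climate clim.csv --crops maize --out cal.csv
cropcal scenarios --n-cells 12 --n-years 10 --seed 1 --out scen.csv
```

The `scenarios` subcommand builds a synthetic grid with baseline /
intermediate / future periods (+4 °C by default), runs the full adaptation
protocol, writes per-cell results, and reports the area-masked mean
timely-adaptation benefit of the yield index (a scenario-ordering
quantity; magnitudes are not comparable to biophysical crop models).

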