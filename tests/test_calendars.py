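"""The rule-based calendar decision model."""

import numpy as np
import pytest

from cropcal.calendars import (
    CalendarConfig,
    CropParams,
    Driver,
    WheatType,
    build_calendar,
    choose_wheat_type,
    maturity_date,
    sowing_date,
)
from cropcal.climate import (
    DAYS_PER_YEAR,
    DailyClimate,
    MonthlyClimate,
    circular_span,
    classify_seasonality,
    first_crossing_day,
    interpolate_monthly_to_daily,
    month_mid_doy,
    coldest_month,
    warmest_month,
    wrap_doy,
)

from conftest import mc_with_coldest, sinusoid_mc


def _daily_ramp_falling_at(doy: int) -> DailyClimate:
    """A daily series whose falling 12 degC crossing lands exactly on *doy*."""
    temp = np.full(DAYS_PER_YEAR, 20.0)
    temp[doy - 1:] = 5.0
    zeros = np.zeros(DAYS_PER_YEAR)
    return DailyClimate(temp, zeros, np.ones(DAYS_PER_YEAR), zeros)


class TestWheatType:
    def test_harsh_winter_forces_spring_wheat(self, crop_params):
        mc = mc_with_coldest(-15.0)
        dc = interpolate_monthly_to_daily(mc)
        assert choose_wheat_type(mc, dc, crop_params["wheat"]) is WheatType.SPRING

    def test_mild_winter_gives_winter_wheat_without_vernalization(self, crop_params):
        mc = mc_with_coldest(2.0)
        dc = interpolate_monthly_to_daily(mc)
        assert choose_wheat_type(mc, dc, crop_params["wheat"]) is WheatType.WINTER_NO_VERN

    @pytest.mark.parametrize(
        "crossing_doy,expected",
        [(274, WheatType.WINTER_VERN), (244, WheatType.SPRING)],  # 1 Oct vs 1 Sep
    )
    def test_long_winter_cutoff_north(self, crop_params, crossing_doy, expected):
        mc = mc_with_coldest(-5.0)
        dc = _daily_ramp_falling_at(crossing_doy)
        assert choose_wheat_type(mc, dc, crop_params["wheat"], "N") is expected

    @pytest.mark.parametrize(
        "crossing_doy,expected",
        [(92, WheatType.WINTER_VERN), (62, WheatType.SPRING)],  # after vs before 31 Mar
    )
    def test_long_winter_cutoff_south(self, crop_params, crossing_doy, expected):
        mc = mc_with_coldest(-5.0)
        dc = _daily_ramp_falling_at(crossing_doy)
        assert choose_wheat_type(mc, dc, crop_params["wheat"], "S") is expected

    def test_breakpoints_at_minus10_and_zero(self, crop_params):
        """The type decision is piecewise-constant in coldest-month
        temperature, switching exactly at -10 and 0 degC."""
        wheat = crop_params["wheat"]
        types = {}
        for coldest in (-10.5, -10.0, -9.5, -0.5, 0.0, 0.5):
            mc = mc_with_coldest(coldest)
            dc = interpolate_monthly_to_daily(mc)
            types[coldest] = choose_wheat_type(mc, dc, wheat, "N")
        assert types[-10.5] is WheatType.SPRING
        assert types[-10.0] is WheatType.SPRING  # "higher than -10" is strict
        assert types[-9.5] in (WheatType.WINTER_VERN, WheatType.SPRING)
        assert types[-0.5] is WheatType.WINTER_VERN
        assert types[0.0] is WheatType.WINTER_VERN  # "higher than 0" is strict
        assert types[0.5] is WheatType.WINTER_NO_VERN

    def test_rejects_non_wheat(self, crop_params):
        mc = mc_with_coldest(-5.0)
        dc = interpolate_monthly_to_daily(mc)
        with pytest.raises(ValueError):
            choose_wheat_type(mc, dc, crop_params["maize"])


class TestSowing:
    def test_winter_wheat_no_vern_sown_75_days_before_coldest_month(self, crop_params):
        mc = mc_with_coldest(2.0)  # coldest is January (mid-DOY 16)
        dc = interpolate_monthly_to_daily(mc)
        assert coldest_month(mc) == 1
        sow, driver = sowing_date(
            mc, dc, crop_params["wheat"], classify_seasonality(mc), "N"
        )
        assert sow == wrap_doy(month_mid_doy(1) - 75)  # wraps into the fall
        assert sow == 306
        assert driver is Driver.TEMP

    def test_precip_cell_sows_at_wet_season_onset(self, crop_params):
        precip = np.zeros(12)
        precip[4:8] = 250.0  # May-Aug wet season
        mc = MonthlyClimate(np.full(12, 26.0), precip, np.full(12, 100.0))
        dc = interpolate_monthly_to_daily(mc)
        sow, driver = sowing_date(mc, dc, crop_params["maize"], classify_seasonality(mc), "N")
        assert driver is Driver.PRECIP
        # oracle: exhaustive window scan over the interpolated daily series
        doubled = np.concatenate((dc.precip_mm, dc.precip_mm))
        sums = [doubled[s:s + 120].sum() for s in range(DAYS_PER_YEAR)]
        assert sow == int(np.argmax(sums)) + 1

    def test_temp_cell_sows_at_rising_threshold_crossing(self, crop_params):
        mc = sinusoid_mc(10.0, 12.0)
        dc = interpolate_monthly_to_daily(mc)
        sow, driver = sowing_date(mc, dc, crop_params["maize"], classify_seasonality(mc), "N")
        assert driver is Driver.TEMP
        # oracle: brute scan for the first rising 14 degC crossing
        expect = next(
            d for d in range(1, DAYS_PER_YEAR + 1)
            if dc.temp_C[(d - 2) % DAYS_PER_YEAR] < 14.0 <= dc.temp_C[d - 1]
        )
        assert sow == expect

    def test_missing_crossing_falls_back_to_default_day(self, crop_params):
        mc = sinusoid_mc(40.0, 12.0)  # always far above the sowing threshold
        dc = interpolate_monthly_to_daily(mc)
        with pytest.warns(UserWarning):
            sow, driver = sowing_date(
                mc, dc, crop_params["maize"], classify_seasonality(mc), "N"
            )
        assert driver is Driver.DEFAULT
        assert sow == CalendarConfig().default_sowing_doy_north

    def test_no_seasonality_uses_hemisphere_default(self, crop_params):
        mc = sinusoid_mc(25.0, 0.0, precip_mm=100.0)
        dc = interpolate_monthly_to_daily(mc)
        sc = classify_seasonality(mc)
        for hemi, expect in (("N", 1), ("S", 182)):
            sow, driver = sowing_date(mc, dc, crop_params["maize"], sc, hemi)
            assert (sow, driver) == (expect, Driver.DEFAULT)


class TestMaturity:
    def test_maize_optimal_summer_grain_fills_from_warmest_month(self, crop_params):
        maize = crop_params["maize"]
        mc = sinusoid_mc(10.0, 12.0)  # July peak of 22 degC: optimal
        dc = interpolate_monthly_to_daily(mc)
        sc = classify_seasonality(mc)
        sow, driver = sowing_date(mc, dc, maize, sc, "N")
        gf, mat = maturity_date(mc, dc, maize, sow, None, sc, driver)
        assert gf == month_mid_doy(7)
        assert circular_span(gf, mat) == 60

    def test_winter_wheat_hot_summer_matures_at_25C_crossing(self, crop_params):
        wheat = crop_params["wheat"]
        mc = mc_with_coldest(2.0, amp_C=13.0)  # warmest month 28 degC
        assert mc.temp_C.max() > 25.0
        dc = interpolate_monthly_to_daily(mc)
        sc = classify_seasonality(mc)
        sow, driver = sowing_date(mc, dc, wheat, sc, "N")
        gf, mat = maturity_date(
            mc, dc, wheat, sow, WheatType.WINTER_NO_VERN, sc, driver
        )
        # oracle: brute scan for the first rising 25 degC crossing after winter
        start = month_mid_doy(coldest_month(mc))
        expect = first_crossing_day(dc.temp_C, 25.0, "rising", search_from=start)
        assert mat == expect
        assert circular_span(gf, mat) == 40

    def test_precip_cell_grain_fills_at_ppet_collapse(self, crop_params):
        maize = crop_params["maize"]
        precip = np.zeros(12)
        precip[3:8] = 220.0
        mc = MonthlyClimate(np.full(12, 27.0), precip, np.full(12, 110.0))
        dc = interpolate_monthly_to_daily(mc)
        sc = classify_seasonality(mc)
        sow, driver = sowing_date(mc, dc, maize, sc, "N")
        gf, mat = maturity_date(mc, dc, maize, sow, None, sc, driver)
        from cropcal.climate import wettest_window_start

        wet_mid = wrap_doy(wettest_window_start(dc) + 60)
        expect = first_crossing_day(dc.p_pet, maize.p_pet_maturity, "falling",
                                    search_from=wet_mid)
        assert gf == expect
        assert circular_span(gf, mat) == 60

    def test_minimum_duration_clamp(self, crop_params):
        # sowing just before the warm peak would give a 77-day season;
        # the clamp pushes maturity out to the 90-day minimum
        maize = crop_params["maize"]
        mc = sinusoid_mc(10.0, 12.0)
        dc = interpolate_monthly_to_daily(mc)
        sc = classify_seasonality(mc)
        gf, mat = maturity_date(mc, dc, maize, 180, None, sc, Driver.TEMP)
        assert circular_span(180, mat) == maize.min_duration_days
        assert circular_span(gf, mat) == maize.gf_duration_days


class TestBuildCalendar:
    def test_deterministic(self, crop_params):
        mc = sinusoid_mc(10.0, 12.0)
        a = build_calendar(mc, crop_params["maize"], "N")
        b = build_calendar(mc, crop_params["maize"], "N")
        assert a == b

    def test_uniform_warming_advances_spring_sowing(self, crop_params):
        mc = sinusoid_mc(9.0, 12.0)
        warmed = MonthlyClimate(mc.temp_C + 4.0, mc.precip_mm, mc.pet_mm)
        a = build_calendar(mc, crop_params["maize"], "N")
        b = build_calendar(warmed, crop_params["maize"], "N")
        assert b.sowing_doy <= a.sowing_doy

    def test_southern_mirror_shifts_calendar_half_a_year(self, crop_params):
        north = sinusoid_mc(10.0, 12.0, peak_doy=197)
        south = sinusoid_mc(10.0, 12.0, peak_doy=wrap_doy(197 + 182))
        a = build_calendar(north, crop_params["maize"], "N")
        b = build_calendar(south, crop_params["maize"], "S")
        shift = circular_span(a.sowing_doy, b.sowing_doy)
        assert shift in (182, 183)

    def test_invariant_to_precip_scaling_in_temp_cells(self, crop_params):
        mc = sinusoid_mc(10.0, 12.0, precip_mm=60.0)
        scaled = MonthlyClimate(mc.temp_C, mc.precip_mm * 3.0, mc.pet_mm)
        a = build_calendar(mc, crop_params["maize"], "N")
        b = build_calendar(scaled, crop_params["maize"], "N")
        assert (a.sowing_doy, a.maturity_doy) == (b.sowing_doy, b.maturity_doy)

    @pytest.mark.parametrize("crop", ["maize", "rice", "sorghum", "soybean", "wheat"])
    def test_grain_filling_window_length(self, crop_params, crop):
        """Grain filling spans exactly 60 days for maize, 40 otherwise,
        whenever no terminal-stress advance fired."""
        mc = sinusoid_mc(12.0, 11.0, precip_mm=90.0, pet_mm=80.0)
        cal = build_calendar(mc, crop_params[crop], "N")
        expect = 60 if crop == "maize" else 40
        assert cal.gf_days == expect


class TestCropParamsValidation:
    def test_invalid_gf_range_rejected(self):
        with pytest.raises(ValueError):
            CropParams(
                name="x", sowing_temp_C=10, base_temp_C=5, gf_opt_min_C=25,
                gf_opt_max_C=20, p_pet_sowing=0.3, p_pet_maturity=0.2,
                gf_duration_days=40, vernalizing=False,
            )

    def test_invalid_gf_duration_rejected(self):
        with pytest.raises(ValueError):
            CropParams(
                name="x", sowing_temp_C=10, base_temp_C=5, gf_opt_min_C=15,
                gf_opt_max_C=25, p_pet_sowing=0.3, p_pet_maturity=0.2,
                gf_duration_days=50, vernalizing=False,
            )
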