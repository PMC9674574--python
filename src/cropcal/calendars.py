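"""Rule-based mean sowing and maturity dates.

The decision model assumes farmers pick growing seasons from the mean
climatic character of their location: under precipitation-driven
seasonality crops are sown at the onset of the main rainy season (the first
day of the wettest 120 consecutive days); under temperature-driven
seasonality spring crops are sown when daily temperature first rises above
a crop-specific threshold.  Maturity is chosen so that grain filling — the
phase most critical for yield formation — sits in the least stressful part
of the year, with a fixed grain-filling duration (60 days for maize, 40
days otherwise).

Wheat is split into three types: winter wheat with vernalization (sown in
fall, dormant over a cold but not-too-harsh winter), winter wheat without
vernalization (mild winters, sown 75 days before the coldest month), and
spring wheat for locations where winters are too harsh or too long for a
winter type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import yaml

from .climate import (
    DailyClimate,
    MonthlyClimate,
    Seasonality,
    SeasonalityClass,
    SeasonalityThresholds,
    circular_span,
    classify_seasonality,
    coldest_month,
    first_crossing_day,
    interpolate_monthly_to_daily,
    month_mid_doy,
    warmest_month,
    wettest_window_start,
    wrap_doy,
)

__all__ = [
    "CropParams",
    "WheatType",
    "Driver",
    "CropCalendar",
    "CalendarConfig",
    "RuleFailure",
    "default_crop_params",
    "choose_wheat_type",
    "sowing_date",
    "maturity_date",
    "build_calendar",
]

SPRING_CROPS = ("maize", "rice", "sorghum", "soybean")

# wheat-type decision constants
WHEAT_SOWING_TEMP_C = 12.0
HARSH_WINTER_C = -10.0
MILD_WINTER_C = 0.0
LONG_WINTER_DOY_N = 258  # 15 September
LONG_WINTER_DOY_S = 90  # 31 March
WINTER_NOVERN_SOWING_OFFSET = 75  # days before the coldest month


class WheatType(str, Enum):
    WINTER_VERN = "WINTER_VERN"
    WINTER_NO_VERN = "WINTER_NO_VERN"
    SPRING = "SPRING"


class Driver(str, Enum):
    TEMP = "TEMP"
    PRECIP = "PRECIP"
    DEFAULT = "DEFAULT"


class RuleFailure(ValueError):
    """A calendar rule produced an inconsistent result; names the branch."""

    def __init__(self, branch: str, message: str):
        self.branch = branch
        super().__init__(f"[{branch}] {message}")


@dataclass(frozen=True)
class CropParams:
    """Global per-crop thresholds for the calendar rules."""

    name: str
    sowing_temp_C: float
    base_temp_C: float
    gf_opt_min_C: float
    gf_opt_max_C: float
    p_pet_sowing: float
    p_pet_maturity: float
    gf_duration_days: int
    vernalizing: bool
    min_duration_days: int = 90
    max_duration_days: int = 330
    wheat_maturity_max_C: float = 25.0

    def __post_init__(self) -> None:
        if not self.gf_opt_min_C < self.gf_opt_max_C:
            raise ValueError("gf_opt_min_C must be < gf_opt_max_C")
        if self.gf_duration_days not in (40, 60):
            raise ValueError("gf_duration_days must be 40 or 60")
        if not self.min_duration_days < self.max_duration_days:
            raise ValueError("min_duration_days must be < max_duration_days")


def default_crop_params(crop: str | None = None) -> CropParams | dict[str, CropParams]:
    """Load the shipped default parameter table (all crops, or one)."""
    with resources.files("cropcal.data").joinpath("crop_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    table = {name: CropParams(name=name, **vals) for name, vals in raw.items()}
    if crop is None:
        return table
    try:
        return table[crop]
    except KeyError:
        raise KeyError(f"unknown crop {crop!r}; known: {sorted(table)}") from None


@dataclass(frozen=True)
class CropCalendar:
    """Mean sowing, grain-filling-start and maturity DOYs for one cell/crop.

    Identical for rainfed and irrigated stands: the rules use only
    climatology, not soil water.
    """

    sowing_doy: int
    gf_start_doy: int
    maturity_doy: int
    wheat_type: WheatType | None = None
    driver: Driver = Driver.TEMP

    @property
    def duration_days(self) -> int:
        return circular_span(self.sowing_doy, self.maturity_doy)

    @property
    def gf_days(self) -> int:
        return circular_span(self.gf_start_doy, self.maturity_doy)


@dataclass(frozen=True)
class CalendarConfig:
    """Knobs of the calendar rules that the source method leaves open."""

    seasonality: SeasonalityThresholds = SeasonalityThresholds()
    default_sowing_doy_north: int = 1
    default_sowing_doy_south: int = 182
    gf_floor_days: int = 10  # terminal-stress advance never shrinks gf below this


def _hemisphere_north(hemisphere: str) -> bool:
    if hemisphere not in ("N", "S"):
        raise ValueError("hemisphere must be 'N' or 'S'")
    return hemisphere == "N"


def choose_wheat_type(
    mc: MonthlyClimate,
    dc: DailyClimate,
    crop: CropParams,
    hemisphere: str = "N",
) -> WheatType:
    """Pick the wheat type grown at a location from its winter character.

    Winter wheat with vernalization needs a real winter (some month below
    0 degC) that is neither too harsh (coldest month above -10 degC) nor too
    long (daily temperature falls below the 12 degC sowing threshold only
    after 15 Sep in the north / 31 Mar in the south).  Mild winters (coldest
    month above 0 degC) grow winter wheat without vernalization; everything
    else falls back to spring wheat.
    """
    if crop.name != "wheat":
        raise ValueError("choose_wheat_type applies to wheat only")
    t_cold = float(mc.temp_C[coldest_month(mc) - 1])
    if t_cold > MILD_WINTER_C:
        return WheatType.WINTER_NO_VERN
    if t_cold <= HARSH_WINTER_C:
        return WheatType.SPRING
    crossing = first_crossing_day(dc.temp_C, WHEAT_SOWING_TEMP_C, "falling")
    if crossing is None:
        return WheatType.SPRING
    cutoff = LONG_WINTER_DOY_N if _hemisphere_north(hemisphere) else LONG_WINTER_DOY_S
    if crossing > cutoff:
        return WheatType.WINTER_VERN
    return WheatType.SPRING


def _temp_precedence(mc: MonthlyClimate, crop: CropParams) -> bool:
    """In mixed-seasonality cells, temperature rules win when winter cold
    (coldest month below the crop sowing threshold) limits growth."""
    t_cold = float(mc.temp_C[coldest_month(mc) - 1])
    return t_cold < crop.sowing_temp_C


def sowing_date(
    mc: MonthlyClimate,
    dc: DailyClimate,
    crop: CropParams,
    seasonality: SeasonalityClass,
    hemisphere: str = "N",
    wheat_type: WheatType | None = None,
    config: CalendarConfig | None = None,
) -> tuple[int, Driver]:
    """Mean sowing DOY and which climate driver set it."""
    config = config or CalendarConfig()
    north = _hemisphere_north(hemisphere)
    default_doy = (
        config.default_sowing_doy_north if north else config.default_sowing_doy_south
    )

    if crop.name == "wheat":
        if wheat_type is None:
            wheat_type = choose_wheat_type(mc, dc, crop, hemisphere)
        if wheat_type is WheatType.WINTER_VERN:
            doy = first_crossing_day(dc.temp_C, WHEAT_SOWING_TEMP_C, "falling")
            if doy is None:  # unreachable when the type decision found one
                raise RuleFailure("winter-vern-sowing", "no falling 12 degC crossing")
            return doy, Driver.TEMP
        if wheat_type is WheatType.WINTER_NO_VERN:
            mid = month_mid_doy(coldest_month(mc))
            return wrap_doy(mid - WINTER_NOVERN_SOWING_OFFSET), Driver.TEMP
        # spring wheat follows the spring-crop rules below

    label = seasonality.label
    use_temp = label in (Seasonality.TEMP, Seasonality.TEMP_PRECIP) and (
        label is Seasonality.TEMP or _temp_precedence(mc, crop)
    )
    use_precip = label is Seasonality.PRECIP or (
        label is Seasonality.TEMP_PRECIP and not use_temp
    )

    if use_precip:
        return wettest_window_start(dc), Driver.PRECIP
    if use_temp:
        doy = first_crossing_day(dc.temp_C, crop.sowing_temp_C, "rising")
        if doy is None:
            warnings.warn(
                f"{crop.name}: no rising {crop.sowing_temp_C} degC crossing; "
                "falling back to the default sowing day",
                stacklevel=2,
            )
            return default_doy, Driver.DEFAULT
        return doy, Driver.TEMP
    return default_doy, Driver.DEFAULT


def maturity_date(
    mc: MonthlyClimate,
    dc: DailyClimate,
    crop: CropParams,
    sowing_doy: int,
    wheat_type: WheatType | None,
    seasonality: SeasonalityClass,
    driver: Driver = Driver.TEMP,
    config: CalendarConfig | None = None,
) -> tuple[int, int]:
    """Grain-filling start and maturity DOYs for a resolved sowing date.

    Temperature-driven cells: spring crops start grain filling in the
    warmest month (or right after temperatures fall back inside the optimal
    range); winter wheat *ends* grain filling in the warmest month (or on
    the day temperatures first exceed the 25 degC terminal-heat cutoff).
    Precipitation-driven cells: grain filling starts toward the end of the
    rainy season, when daily P/PET falls below the crop threshold.  In all
    cases maturity is advanced to escape terminal water stress when P/PET
    collapses during grain filling, and the total growing period is clamped
    to the crop's plausible duration range.
    """
    config = config or CalendarConfig()
    gf_len = crop.gf_duration_days
    warm_mid = month_mid_doy(warmest_month(mc))
    t_warm = float(mc.temp_C[warmest_month(mc) - 1])

    is_winter_wheat = wheat_type in (WheatType.WINTER_VERN, WheatType.WINTER_NO_VERN)

    if is_winter_wheat:
        if t_warm <= crop.wheat_maturity_max_C:
            maturity = warm_mid
            branch = "winter-warmest-month"
        else:
            maturity = first_crossing_day(
                dc.temp_C,
                crop.wheat_maturity_max_C,
                "rising",
                search_from=month_mid_doy(coldest_month(mc)),
            )
            branch = "winter-terminal-heat"
            if maturity is None:  # cannot happen when t_warm exceeds the cutoff
                maturity = warm_mid
                branch = "winter-warmest-month"
        gf_start = wrap_doy(maturity - gf_len)
    elif driver is Driver.PRECIP:
        wet_start = wettest_window_start(dc)
        wet_mid = wrap_doy(wet_start + 60)
        gf_start = first_crossing_day(
            dc.p_pet, crop.p_pet_maturity, "falling", search_from=wet_mid
        )
        branch = "precip-ppet-crossing"
        if gf_start is None:
            gf_start = wrap_doy(wet_start + 120)  # end of the wet season
            branch = "precip-wet-season-end"
        maturity = wrap_doy(gf_start + gf_len)
    else:
        if t_warm <= crop.gf_opt_max_C:
            gf_start = warm_mid
            branch = "spring-warmest-month"
        else:
            gf_start = first_crossing_day(
                dc.temp_C, crop.gf_opt_max_C, "falling", search_from=warm_mid
            )
            branch = "spring-above-optimal"
            if gf_start is None:  # temperatures never drop back below the optimum
                gf_start = warm_mid
                branch = "spring-warmest-month"
        maturity = wrap_doy(gf_start + gf_len)

    # terminal water stress: advance maturity to the P/PET collapse, never
    # shrinking grain filling below the floor nor the season below minimum
    stress = first_crossing_day(
        dc.p_pet, crop.p_pet_maturity, "falling", search_from=gf_start
    )
    if stress is not None:
        new_span = circular_span(sowing_doy, stress)
        gf_span = circular_span(gf_start, stress)
        if (
            new_span < circular_span(sowing_doy, maturity)
            and new_span >= crop.min_duration_days
            and config.gf_floor_days <= gf_span <= gf_len
        ):
            maturity = stress
            branch += "+terminal-water-stress"

    # clamp the full growing period
    span = circular_span(sowing_doy, maturity)
    if span < crop.min_duration_days:
        maturity = wrap_doy(sowing_doy + crop.min_duration_days)
        gf_start = wrap_doy(maturity - gf_len)
        branch += "+min-clamp"
    elif span > crop.max_duration_days:
        maturity = wrap_doy(sowing_doy + crop.max_duration_days)
        gf_start = wrap_doy(maturity - gf_len)
        branch += "+max-clamp"

    if circular_span(sowing_doy, gf_start) >= circular_span(sowing_doy, maturity):
        raise RuleFailure(
            branch,
            f"grain filling start DOY {gf_start} not inside the growing period "
            f"(sowing {sowing_doy}, maturity {maturity})",
        )
    return gf_start, maturity


def build_calendar(
    mc: MonthlyClimate,
    crop: CropParams,
    hemisphere: str = "N",
    config: CalendarConfig | None = None,
    dc: DailyClimate | None = None,
) -> CropCalendar:
    """Compose the full rule chain into a calendar for one cell and crop.

    Deterministic, and identical for rainfed and irrigated water regimes.
    """
    config = config or CalendarConfig()
    dc = dc or interpolate_monthly_to_daily(mc)
    seasonality = classify_seasonality(mc, config.seasonality)
    wheat_type = (
        choose_wheat_type(mc, dc, crop, hemisphere) if crop.name == "wheat" else None
    )
    sow, driver = sowing_date(
        mc, dc, crop, seasonality, hemisphere, wheat_type=wheat_type, config=config
    )
    gf_start, maturity = maturity_date(
        mc, dc, crop, sow, wheat_type, seasonality, driver=driver, config=config
    )
    return CropCalendar(
        sowing_doy=sow,
        gf_start_doy=gf_start,
        maturity_doy=maturity,
        wheat_type=wheat_type,
        driver=driver,
    )
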