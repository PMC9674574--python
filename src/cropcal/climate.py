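"""Climate data model and the search primitives the calendar rules depend on.

All calendar arithmetic uses a 365-day no-leap year with 1-based day-of-year
(DOY) and circular wrap-around: the rules operate on long-term monthly
climatologies, so leap days carry no information.  Daily series are derived
from monthly means by piecewise-linear interpolation between mid-month
anchors, wrapping December back to January.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "MONTH_LENGTHS",
    "MONTH_MID_DOY",
    "DAYS_PER_YEAR",
    "MonthlyClimate",
    "DailyClimate",
    "Seasonality",
    "SeasonalityClass",
    "TemperatureLevel",
    "SeasonalityThresholds",
    "wrap_doy",
    "circular_span",
    "interpolate_monthly_to_daily",
    "classify_seasonality",
    "classify_temperature_level",
    "wettest_window_start",
    "first_crossing_day",
    "warmest_month",
    "coldest_month",
]

DAYS_PER_YEAR = 365

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# mid-month anchor DOY (float): first day of month + (length - 1) / 2
_month_starts = np.concatenate(([0], np.cumsum(MONTH_LENGTHS)[:-1])) + 1
MONTH_MID_DOY = _month_starts + (MONTH_LENGTHS - 1) / 2.0

# P/PET sentinel where PET == 0: rules only ever test "falls below a
# threshold", so an effectively infinite ratio means "no water limitation".
P_PET_SENTINEL = 1.0e6

_KELVIN = 273.15


def wrap_doy(doy: float | int) -> int:
    """Wrap any integer day offset onto the 1..365 circular calendar."""
    return int((int(round(doy)) - 1) % DAYS_PER_YEAR) + 1


def circular_span(start_doy: int, end_doy: int) -> int:
    """Days from *start_doy* to *end_doy* walking forward circularly.

    Equal start and end count as a full 365-day cycle, never zero: a crop
    sown and maturing on the same DOY occupied the whole year.
    """
    span = (end_doy - start_doy) % DAYS_PER_YEAR
    return DAYS_PER_YEAR if span == 0 else span


@dataclass(frozen=True)
class MonthlyClimate:
    """Monthly climatology for one grid cell.

    Parameters
    ----------
    temp_C : array-like of 12 monthly mean temperatures (degC).
    precip_mm : array-like of 12 monthly precipitation totals (mm/month).
    pet_mm : array-like of 12 monthly potential evapotranspiration totals
        (mm/month).
    """

    temp_C: np.ndarray
    precip_mm: np.ndarray
    pet_mm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("temp_C", "precip_mm", "pet_mm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have exactly 12 entries")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)
        if np.any(self.precip_mm < 0):
            raise ValueError("precip_mm must be non-negative")
        if np.any(self.pet_mm < 0):
            raise ValueError("pet_mm must be non-negative")


@dataclass(frozen=True)
class DailyClimate:
    """365-day daily climatology interpolated from monthly means.

    ``temp_C`` is degC; ``precip_mm`` and ``pet_mm`` are per-day rates
    (mm/day); ``p_pet`` is the daily precipitation / potential
    evapotranspiration ratio (dimensionless, sentinel where PET is zero).
    Index 0 corresponds to DOY 1.
    """

    temp_C: np.ndarray
    precip_mm: np.ndarray
    pet_mm: np.ndarray
    p_pet: np.ndarray

    def __post_init__(self) -> None:
        for name in ("temp_C", "precip_mm", "pet_mm", "p_pet"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (DAYS_PER_YEAR,):
                raise ValueError(f"{name} must have exactly {DAYS_PER_YEAR} entries")
            object.__setattr__(self, name, arr)

    def at(self, doy: int, name: str = "temp_C") -> float:
        return float(getattr(self, name)[wrap_doy(doy) - 1])


class Seasonality(str, Enum):
    NO_SEASONALITY = "NO_SEASONALITY"
    PRECIP = "PRECIP"
    TEMP = "TEMP"
    TEMP_PRECIP = "TEMP_PRECIP"


class TemperatureLevel(str, Enum):
    BELOW_OPTIMAL = "BELOW_OPTIMAL"
    OPTIMAL = "OPTIMAL"
    ABOVE_OPTIMAL = "ABOVE_OPTIMAL"


@dataclass(frozen=True)
class SeasonalityThresholds:
    """Coefficient-of-variation thresholds for the seasonality classifier.

    ``cv_temp_min`` applies to monthly temperature expressed in kelvin
    (an absolute scale avoids the sign/zero-mean pathologies of degC);
    ``cv_prec_min`` applies to monthly precipitation totals.
    """

    cv_temp_min: float = 0.01
    cv_prec_min: float = 0.4


@dataclass(frozen=True)
class SeasonalityClass:
    label: Seasonality
    cv_temp: float
    cv_prec: float


def interpolate_monthly_to_daily(mc: MonthlyClimate) -> DailyClimate:
    """Build a 365-day daily climatology by linear interpolation.

    Temperatures interpolate directly between mid-month anchors; monthly
    precipitation and PET totals are first converted to per-day rates so
    that the interpolated series has mm/day units.  Interpolation wraps
    circularly (December -> January).
    """
    doys = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    temp = _circular_interp(doys, MONTH_MID_DOY, mc.temp_C)
    precip = _circular_interp(doys, MONTH_MID_DOY, mc.precip_mm / MONTH_LENGTHS)
    pet = _circular_interp(doys, MONTH_MID_DOY, mc.pet_mm / MONTH_LENGTHS)
    precip = np.maximum(precip, 0.0)
    pet = np.maximum(pet, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_pet = np.where(pet > 0, precip / np.where(pet > 0, pet, 1.0), P_PET_SENTINEL)
    return DailyClimate(temp_C=temp, precip_mm=precip, pet_mm=pet, p_pet=p_pet)


def _circular_interp(x: np.ndarray, anchors: np.ndarray, values: np.ndarray) -> np.ndarray:
    # pad one anchor on each side from the opposite end of the year
    ax = np.concatenate(([anchors[-1] - DAYS_PER_YEAR], anchors, [anchors[0] + DAYS_PER_YEAR]))
    av = np.concatenate(([values[-1]], values, [values[0]]))
    return np.interp(x, ax, av)


def classify_seasonality(
    mc: MonthlyClimate, thresholds: SeasonalityThresholds | None = None
) -> SeasonalityClass:
    """Classify a cell's climate by which driver structures its year.

    The coefficient of variation (sample sd / mean) of the 12 monthly values
    is computed for temperature (in kelvin) and precipitation; exceeding the
    respective threshold marks that driver as seasonal.
    """
    thresholds = thresholds or SeasonalityThresholds()
    cv_temp = _cv(mc.temp_C + _KELVIN)
    cv_prec = _cv(mc.precip_mm)
    temp_seasonal = cv_temp > thresholds.cv_temp_min
    prec_seasonal = cv_prec > thresholds.cv_prec_min
    if temp_seasonal and prec_seasonal:
        label = Seasonality.TEMP_PRECIP
    elif temp_seasonal:
        label = Seasonality.TEMP
    elif prec_seasonal:
        label = Seasonality.PRECIP
    else:
        label = Seasonality.NO_SEASONALITY
    return SeasonalityClass(label=label, cv_temp=cv_temp, cv_prec=cv_prec)


def _cv(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0.0:
        return 0.0
    return float(np.std(values, ddof=1) / mean)


def wettest_window_start(dc: DailyClimate, window_days: int = 120) -> int:
    """First DOY of the circular *window_days*-day window with the largest
    summed precipitation; ties resolve to the earliest start day.
    """
    if not 1 <= window_days <= DAYS_PER_YEAR:
        raise ValueError("window_days must be in [1, 365]")
    precip = dc.precip_mm
    doubled = np.concatenate((precip, precip))
    csum = np.concatenate(([0.0], np.cumsum(doubled)))
    sums = csum[window_days : window_days + DAYS_PER_YEAR] - csum[:DAYS_PER_YEAR]
    return int(np.argmax(sums)) + 1


def first_crossing_day(
    series: np.ndarray,
    threshold: float,
    direction: str,
    search_from: int = 1,
) -> int | None:
    """First circular DOY at/after *search_from* where *series* crosses
    *threshold* in the given direction.

    A rising crossing at day d means series[d-1] < threshold <= series[d];
    a falling crossing means series[d-1] > threshold >= series[d].  If the
    threshold is met for a run of days the first day of the run is returned.
    Returns ``None`` when no crossing exists anywhere in the cycle.
    """
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    series = np.asarray(series, dtype=float)
    if series.shape != (DAYS_PER_YEAR,):
        raise ValueError("series must have exactly 365 entries")
    start = wrap_doy(search_from)
    for offset in range(DAYS_PER_YEAR):
        doy = wrap_doy(start + offset)
        prev = series[wrap_doy(doy - 1) - 1]
        cur = series[doy - 1]
        if direction == "rising" and prev < threshold <= cur:
            return doy
        if direction == "falling" and prev > threshold >= cur:
            return doy
    return None


def warmest_month(mc: MonthlyClimate) -> int:
    """1-based index of the warmest month (earliest month on ties)."""
    return int(np.argmax(mc.temp_C)) + 1


def coldest_month(mc: MonthlyClimate) -> int:
    """1-based index of the coldest month (earliest month on ties)."""
    return int(np.argmin(mc.temp_C)) + 1


def month_mid_doy(month: int) -> int:
    """Integer DOY of the mid-month anchor of 1-based *month*."""
    return wrap_doy(MONTH_MID_DOY[month - 1])


def classify_temperature_level(mc: MonthlyClimate, crop) -> TemperatureLevel:
    """Compare the warmest-month temperature against a crop's optimal
    grain-filling range."""
    t_warm = float(mc.temp_C[warmest_month(mc) - 1])
    if t_warm > crop.gf_opt_max_C:
        return TemperatureLevel.ABOVE_OPTIMAL
    if t_warm < crop.gf_opt_min_C:
        return TemperatureLevel.BELOW_OPTIMAL
    return TemperatureLevel.OPTIMAL
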