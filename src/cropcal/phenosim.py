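"""Daily forward simulation of crop phenology for a prescribed sowing date
and cultivar.

From sowing, effective thermal units (mean temperature above the crop base
temperature, vernalization-scaled for winter cultivars) accumulate daily;
maturity is the first day the cultivar's requirement ``tu_req`` is met.
The harvest-index curve ties yield formation to phenological progress
fTU (fraction of ``tu_req`` fulfilled):

    fHI = 100 * fTU / (100 * fTU + exp(11.1 - 10.0 * fTU))

so the bulk of the storage organs fills after ~40% of the thermal
requirement.  A leaf-area plateau at 45% (wheat) / 50% (other crops) of
fTU serves as a flowering-stage proxy, and a frost event (daily minimum
below -5 degC) during grain yield formation (0.5 < fTU < 0.95) fails the
crop.

``toy_yield`` is a deliberately simple relative-yield stand-in — a
temperature-suitability accumulation times the final harvest index — whose
only contracts are determinism and a monotone response to season
suitability.  It is not a biophysical growth model and its magnitudes carry
no meaning beyond scenario ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendars import CropParams
from .climate import DAYS_PER_YEAR, DailyClimate
from .cultivars import (
    VERN_FREE_FRACTION,
    CultivarParams,
    effective_tu_increments,
    vu_effectiveness,
)

__all__ = [
    "DailyWeather",
    "PhenologyTrace",
    "weather_from_daily_climate",
    "simulate_phenology",
    "fhi",
    "flowering_proxy",
    "frost_failure",
    "toy_yield",
]

FROST_TMIN_C = -5.0
FROST_FPHU_MIN = 0.5
FROST_FPHU_MAX = 0.95
DEFAULT_TMIN_OFFSET_C = 5.0
DEFAULT_HORIZON_DAYS = 365


@dataclass(frozen=True)
class DailyWeather:
    """Daily weather series; index 0 is the sowing day."""

    temp_mean_C: np.ndarray
    temp_min_C: np.ndarray
    precip_mm: np.ndarray
    pet_mm: np.ndarray

    def __post_init__(self) -> None:
        n = len(np.asarray(self.temp_mean_C))
        for name in ("temp_mean_C", "temp_min_C", "precip_mm", "pet_mm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError("all weather series must have equal length")
            object.__setattr__(self, name, arr)
        if np.any(self.temp_min_C > self.temp_mean_C):
            raise ValueError("temp_min_C must not exceed temp_mean_C")

    def __len__(self) -> int:
        return len(self.temp_mean_C)


def weather_from_daily_climate(
    dc: DailyClimate,
    sowing_doy: int,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    tmin_offset_C: float = DEFAULT_TMIN_OFFSET_C,
) -> DailyWeather:
    """Unroll a daily climatology circularly from a sowing day.

    Daily minimum temperature defaults to mean minus ``tmin_offset_C``; real
    forcing with observed minima should be supplied directly.
    """
    idx = (sowing_doy - 1 + np.arange(horizon_days)) % DAYS_PER_YEAR
    temps = dc.temp_C[idx]
    return DailyWeather(
        temp_mean_C=temps,
        temp_min_C=temps - tmin_offset_C,
        precip_mm=dc.precip_mm[idx],
        pet_mm=dc.pet_mm[idx],
    )


@dataclass(frozen=True)
class PhenologyTrace:
    """Per-day accumulation record of one simulated crop cycle.

    Arrays are indexed by day after sowing (0 = sowing day); summary fields
    are 1-based days after sowing.  ``maturity_day`` is ``None`` when the
    thermal requirement was not met within the horizon.
    """

    tu_acc: np.ndarray
    vu_acc: np.ndarray
    vern_multiplier: np.ndarray
    f_tu: np.ndarray
    f_hi: np.ndarray
    maturity_day: int | None
    flowering_proxy_day: int | None
    frost_failure: bool
    cultivar: CultivarParams

    @property
    def matured(self) -> bool:
        return self.maturity_day is not None


def fhi(f_tu):
    """Harvest-index fraction as a function of phenological progress."""
    f = np.asarray(f_tu, dtype=float)
    out = 100.0 * f / (100.0 * f + np.exp(11.1 - 10.0 * f))
    return float(out) if np.isscalar(f_tu) else out


def _flowering_threshold(crop_name: str) -> float:
    return 0.45 if crop_name == "wheat" else 0.50


def simulate_phenology(
    weather: DailyWeather,
    sowing_doy: int,
    cultivar: CultivarParams,
    crop: CropParams,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
) -> PhenologyTrace:
    """Run the daily thermal-time / vernalization loop from sowing.

    Non-maturation within the horizon is a reported outcome (``maturity_day
    is None``), not an error.  The simulation is deterministic.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    if cultivar.crop != crop.name:
        raise ValueError(
            f"cultivar is for {cultivar.crop!r}, crop parameters for {crop.name!r}"
        )
    n = min(horizon_days, len(weather))
    temps = weather.temp_mean_C[:n]

    increments = effective_tu_increments(temps, crop.base_temp_C, cultivar.vu_req)
    tu_acc = np.cumsum(increments)
    vu_acc = np.cumsum(vu_effectiveness(temps))
    if cultivar.vu_req > 0:
        progress = np.minimum(1.0, vu_acc / cultivar.vu_req)
        multiplier = np.where(progress < VERN_FREE_FRACTION, 1.0, progress)
    else:
        multiplier = np.ones(n)

    if cultivar.tu_req <= 0.0:
        f_tu = np.ones(n)
        maturity_day = 1
    else:
        f_tu = np.minimum(1.0, tu_acc / cultivar.tu_req)
        reached = np.nonzero(tu_acc >= cultivar.tu_req)[0]
        maturity_day = int(reached[0]) + 1 if reached.size else None

    f_hi = fhi(f_tu)

    flowering = np.nonzero(f_tu >= _flowering_threshold(crop.name))[0]
    flowering_day = int(flowering[0]) + 1 if flowering.size else None

    last = maturity_day if maturity_day is not None else n
    in_window = (f_tu[:last] > FROST_FPHU_MIN) & (f_tu[:last] < FROST_FPHU_MAX)
    frost = bool(np.any(in_window & (weather.temp_min_C[:last] < FROST_TMIN_C)))

    return PhenologyTrace(
        tu_acc=tu_acc,
        vu_acc=vu_acc,
        vern_multiplier=multiplier,
        f_tu=f_tu,
        f_hi=f_hi,
        maturity_day=maturity_day,
        flowering_proxy_day=flowering_day,
        frost_failure=frost,
        cultivar=cultivar,
    )


def flowering_proxy(trace: PhenologyTrace, crop: CropParams) -> int | None:
    """First day (1-based, after sowing) the leaf-area plateau fraction of
    thermal progress is reached: 45% for wheat, 50% for the other crops."""
    threshold = _flowering_threshold(crop.name)
    if trace.cultivar.tu_req <= 0.0:
        return 1
    idx = np.nonzero(trace.f_tu >= threshold)[0]
    return int(idx[0]) + 1 if idx.size else None


def frost_failure(trace: PhenologyTrace, weather: DailyWeather) -> bool:
    """True iff a daily minimum below -5 degC falls strictly inside the
    grain-yield-formation window 0.5 < fTU < 0.95."""
    n = len(trace.f_tu)
    last = trace.maturity_day if trace.maturity_day is not None else n
    in_window = (trace.f_tu[:last] > FROST_FPHU_MIN) & (trace.f_tu[:last] < FROST_FPHU_MAX)
    return bool(np.any(in_window & (weather.temp_min_C[:last] < FROST_TMIN_C)))


def _temperature_suitability(temps: np.ndarray, crop: CropParams) -> np.ndarray:
    """Trapezoidal daily suitability in [0, 1]: zero at/below the base
    temperature, one inside the optimal grain-filling range, falling back to
    zero 10 degC above the range maximum."""
    upper_zero = crop.gf_opt_max_C + 10.0
    rise = (temps - crop.base_temp_C) / max(crop.gf_opt_min_C - crop.base_temp_C, 1e-9)
    fall = (upper_zero - temps) / 10.0
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def toy_yield(trace: PhenologyTrace, weather: DailyWeather, crop: CropParams) -> float:
    """Relative yield index: summed daily temperature suitability over the
    realized growing period, scaled by the final harvest index; zero on
    frost failure or non-maturation.

    Longer suitable seasons therefore never yield less than shorter ones
    under identical weather — the monotonicity the scenario machinery needs
    — but magnitudes are meaningless outside scenario comparisons.
    """
    if trace.frost_failure or trace.maturity_day is None:
        return 0.0
    n = trace.maturity_day
    suit = _temperature_suitability(weather.temp_mean_C[:n], crop)
    return float(suit.sum() * trace.f_hi[n - 1])
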