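"""Cultivar parameterization: thermal-unit and vernalization requirements.

A cultivar adapted to a location is summarized by two numbers derived from
the local climatology and the rule-based calendar:

* ``tu_req`` — thermal units (degC day) accumulated between sowing and
  maturity as daily mean temperature increments above the crop base
  temperature, scaled by vernalization progress for vernalizing cultivars;
* ``vu_req`` — effective vernalization days required before full-speed
  development, between 0 (mild winters) and 70 (cold winters), set by the
  mean temperature of the five coldest months:

  each of the five months contributes (70/5) * (1 - (T_m - 3)/(10 - 3)),
  clamped to [0, 14], so the total lies in [0, 70].

Daily vernalization effectiveness is a three-stage linear response: zero
outside (-4, 17) degC, one on the 3-10 degC optimum plateau, with linear
ramps (T + 4)/7 and (17 - T)/7 on the flanks.

Vernalization slows thermal-unit accumulation by the fraction of ``vu_req``
fulfilled — except during the first 10% of the requirement, where the
multiplier is held at one so the crop can put on some leaf growth in fall
before winter dormancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendars import CropCalendar, CropParams, WheatType
from .climate import DAYS_PER_YEAR, DailyClimate, MonthlyClimate, circular_span

__all__ = [
    "VU_REQ_MAX",
    "CultivarParams",
    "vu_req",
    "vu_effectiveness",
    "effective_tu_increments",
    "tu_req_from_calendar",
]

VU_REQ_MAX = 70.0
_N_COLDEST = 5
_VERN_T_COLD = 3.0  # cold edge of the optimal vernalization range (degC)
_VERN_T_MILD = 10.0  # warm edge; above this a month contributes nothing
VERN_FREE_FRACTION = 0.1  # fraction of vu_req accumulated at full TU speed


@dataclass(frozen=True)
class CultivarParams:
    """A cultivar defined by its thermal and vernalization requirements."""

    crop: str
    tu_req: float
    vu_req: float = 0.0
    source_period: str = ""

    def __post_init__(self) -> None:
        if self.tu_req < 0:
            raise ValueError("tu_req must be >= 0")
        if not 0.0 <= self.vu_req <= VU_REQ_MAX:
            raise ValueError(f"vu_req must lie in [0, {VU_REQ_MAX}]")


def vu_req(mc: MonthlyClimate) -> float:
    """Required effective vernalization days from the 5 coldest months."""
    coldest = np.sort(mc.temp_C)[:_N_COLDEST]
    per_month = (VU_REQ_MAX / _N_COLDEST) * (
        1.0 - (coldest - _VERN_T_COLD) / (_VERN_T_MILD - _VERN_T_COLD)
    )
    per_month = np.clip(per_month, 0.0, VU_REQ_MAX / _N_COLDEST)
    return float(per_month.sum())


def vu_effectiveness(t_d):
    """Daily vernalization effectiveness in [0, 1] (vectorized over t_d)."""
    t = np.asarray(t_d, dtype=float)
    out = np.zeros_like(t)
    lower = (t > -4.0) & (t < 3.0)
    upper = (t > 10.0) & (t < 17.0)
    plateau = (t >= 3.0) & (t <= 10.0)
    out[lower] = (t[lower] + 4.0) / 7.0
    out[upper] = (17.0 - t[upper]) / 7.0
    out[plateau] = 1.0
    if np.isscalar(t_d):
        return float(out)
    return out


def effective_tu_increments(
    temp_C: np.ndarray,
    base_temp_C: float,
    vu_requirement: float = 0.0,
    free_fraction: float = VERN_FREE_FRACTION,
) -> np.ndarray:
    """Per-day effective thermal-unit increments for a daily temperature
    series starting at sowing.

    The vernalization multiplier on day d uses the vernalization units
    accumulated through day d (inclusive): one while progress is below
    *free_fraction*, the raw progress fraction (capped at one) afterwards.
    This single routine backs both cultivar calibration and the forward
    phenology simulator, so the two agree to the last bit.
    """
    temp_C = np.asarray(temp_C, dtype=float)
    raw = np.maximum(0.0, temp_C - base_temp_C)
    if vu_requirement <= 0.0:
        return raw
    vu_acc = np.cumsum(vu_effectiveness(temp_C))
    progress = np.minimum(1.0, vu_acc / vu_requirement)
    multiplier = np.where(progress < free_fraction, 1.0, progress)
    return raw * multiplier


def tu_req_from_calendar(
    dc: DailyClimate,
    calendar: CropCalendar,
    crop: CropParams,
    mc: MonthlyClimate | None = None,
    source_period: str = "",
) -> CultivarParams:
    """Calibrate a cultivar to a rule-based calendar on its own climate.

    Walks the days from sowing to maturity (circularly) accumulating
    effective thermal units; for vernalizing winter wheat the requirement
    ``vu_req`` is taken from the monthly climatology and the accumulation is
    vernalization-scaled.
    """
    ndays = circular_span(calendar.sowing_doy, calendar.maturity_doy)
    if ndays <= 0:
        raise ValueError("zero-length calendar")
    idx = (calendar.sowing_doy - 1 + np.arange(ndays)) % DAYS_PER_YEAR
    temps = dc.temp_C[idx]

    vern = crop.vernalizing and calendar.wheat_type is WheatType.WINTER_VERN
    requirement = 0.0
    if vern:
        if mc is None:
            raise ValueError("monthly climate needed to derive vu_req for "
                             "vernalizing winter wheat")
        requirement = vu_req(mc)

    increments = effective_tu_increments(temps, crop.base_temp_C, requirement)
    # sequential cumulative sum, so the forward simulator (which tests the
    # running total against tu_req) reproduces the calibration bit-for-bit
    total = float(np.cumsum(increments)[-1]) if ndays else 0.0
    return CultivarParams(
        crop=crop.name,
        tu_req=total,
        vu_req=requirement,
        source_period=source_period,
    )
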