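"""Seeded synthetic climate: cells, perturbations, interannual weather.

The generator produces the climate structures the calendar rules assume —
temperature-seasonal (extratropical) cells with a sinusoidal annual
temperature cycle, precipitation-seasonal (tropical) cells with rainfall
concentrated in a wet season, mixed cells, and aseasonal cells — plus
uniform-warming / precipitation-scaling perturbations standing in for
climate-change periods, and autocorrelated interannual weather
realizations around a climatology.

PET is modeled as a simple increasing linear function of monthly
temperature (floored at zero); that is all the P/PET threshold logic
requires.  Every stochastic element takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .climate import (
    DAYS_PER_YEAR,
    MONTH_LENGTHS,
    MONTH_MID_DOY,
    DailyClimate,
    MonthlyClimate,
    interpolate_monthly_to_daily,
)
from .phenosim import DEFAULT_TMIN_OFFSET_C, DailyWeather

__all__ = [
    "PET_BASE_MM_MONTH",
    "PET_SLOPE_MM_MONTH_PER_C",
    "CellSpec",
    "PerturbationSpec",
    "gen_monthly_climatology",
    "apply_perturbation",
    "gen_interannual_weather",
    "preset",
    "mixed_grid_specs",
    "PRESETS",
]

# monthly PET = max(0, base + slope * T_m) mm/month
PET_BASE_MM_MONTH = 10.0
PET_SLOPE_MM_MONTH_PER_C = 4.0


@dataclass(frozen=True)
class CellSpec:
    """Parameters of one synthetic grid cell's climatology."""

    latitude: float = 45.0
    t_mean_C: float = 10.0
    t_amp_C: float = 12.0  # half peak-to-trough amplitude of the annual cycle
    t_peak_doy: int = 197  # mid-July for a northern cell
    p_annual_mm: float = 800.0
    p_concentration: float = 0.4  # fraction of annual rain inside the wet season
    wet_center_doy: int = 197
    wet_season_days: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_amp_C < 0:
            raise ValueError("t_amp_C must be >= 0")
        if not 0.0 <= self.p_concentration <= 1.0:
            raise ValueError("p_concentration must lie in [0, 1]")


@dataclass(frozen=True)
class PerturbationSpec:
    """A climate-period perturbation applied to a cell climatology."""

    label: str = "baseline"
    delta_t_C: float | np.ndarray = 0.0  # uniform or 12-month resolved
    precip_scale: float | np.ndarray = 1.0  # multiplicative, > 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.precip_scale) <= 0):
            raise ValueError("precip_scale must be > 0")


def _pet_from_temp(temp_C: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, PET_BASE_MM_MONTH + PET_SLOPE_MM_MONTH_PER_C * temp_C)


def gen_monthly_climatology(spec: CellSpec) -> MonthlyClimate:
    """Deterministic monthly climatology for a cell spec.

    Temperature is sinusoidal around ``t_mean_C`` peaking at
    ``t_peak_doy``; ``p_concentration`` of the annual precipitation falls
    uniformly inside the circular wet season, the rest uniformly outside.
    """
    temp = spec.t_mean_C + spec.t_amp_C * np.cos(
        2.0 * np.pi * (MONTH_MID_DOY - spec.t_peak_doy) / DAYS_PER_YEAR
    )

    # daily precipitation rate, then aggregate to monthly totals
    doys = np.arange(1, DAYS_PER_YEAR + 1)
    half = spec.wet_season_days / 2.0
    dist = np.minimum(
        np.abs(doys - spec.wet_center_doy),
        DAYS_PER_YEAR - np.abs(doys - spec.wet_center_doy),
    )
    in_wet = dist < half
    n_wet = max(int(in_wet.sum()), 1)
    n_dry = DAYS_PER_YEAR - n_wet
    daily = np.empty(DAYS_PER_YEAR)
    daily[in_wet] = spec.p_annual_mm * spec.p_concentration / n_wet
    if n_dry > 0:
        daily[~in_wet] = spec.p_annual_mm * (1.0 - spec.p_concentration) / n_dry
    month_edges = np.concatenate(([0], np.cumsum(MONTH_LENGTHS)))
    precip = np.array(
        [daily[month_edges[m] : month_edges[m + 1]].sum() for m in range(12)]
    )

    return MonthlyClimate(temp_C=temp, precip_mm=precip, pet_mm=_pet_from_temp(temp))


def apply_perturbation(mc: MonthlyClimate, pert: PerturbationSpec) -> MonthlyClimate:
    """Shift temperatures, scale precipitation, and adjust PET consistently
    with its linear temperature link."""
    delta = np.broadcast_to(np.asarray(pert.delta_t_C, dtype=float), (12,))
    scale = np.broadcast_to(np.asarray(pert.precip_scale, dtype=float), (12,))
    temp = mc.temp_C + delta
    pet = np.maximum(0.0, mc.pet_mm + PET_SLOPE_MM_MONTH_PER_C * delta)
    return MonthlyClimate(temp_C=temp, precip_mm=mc.precip_mm * scale, pet_mm=pet)


def gen_interannual_weather(
    mc: MonthlyClimate,
    years: int,
    anomaly_sd: tuple[float, float] = (1.0, 0.5),
    seed: int = 0,
    persistence: float = 0.8,
    tmin_offset_C: float = DEFAULT_TMIN_OFFSET_C,
    start_doy: int = 1,
) -> list[DailyWeather]:
    """Generate *years* daily weather realizations around a climatology.

    Each year is the interpolated daily climatology plus first-order
    autocorrelated anomalies: additive for temperature (sd in degC) and for
    daily precipitation (sd in mm/day, floored at zero).  Reproducible under
    a fixed seed; ``anomaly_sd=(0, 0)`` returns the climatology each year.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    t_sd, p_sd = anomaly_sd
    rng = np.random.default_rng(seed)
    dc = interpolate_monthly_to_daily(mc)
    idx = (start_doy - 1 + np.arange(DAYS_PER_YEAR)) % DAYS_PER_YEAR

    out = []
    innovation_scale = np.sqrt(max(1.0 - persistence**2, 0.0))
    for _ in range(years):
        t_anom = _ar1(rng, DAYS_PER_YEAR, t_sd, persistence, innovation_scale)
        p_anom = _ar1(rng, DAYS_PER_YEAR, p_sd, persistence, innovation_scale)
        temps = dc.temp_C[idx] + t_anom
        precip = np.maximum(0.0, dc.precip_mm[idx] + p_anom)
        out.append(
            DailyWeather(
                temp_mean_C=temps,
                temp_min_C=temps - tmin_offset_C,
                precip_mm=precip,
                pet_mm=dc.pet_mm[idx],
            )
        )
    return out


def _ar1(rng, n: int, sd: float, rho: float, innov_scale: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, sd * innov_scale, n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


PRESETS: dict[str, CellSpec] = {
    # rain-concentrated, aseasonal-temperature tropics
    "tropical": CellSpec(
        latitude=10.0, t_mean_C=26.0, t_amp_C=1.5, t_peak_doy=105,
        p_annual_mm=1400.0, p_concentration=0.85, wet_center_doy=180,
    ),
    # classic mid-latitude temperature seasonality, year-round rain
    "temperate": CellSpec(
        latitude=48.0, t_mean_C=9.0, t_amp_C=11.0, t_peak_doy=197,
        p_annual_mm=750.0, p_concentration=0.35, wet_center_doy=197,
    ),
    # hot dry summers, wet mild winters
    "mediterranean": CellSpec(
        latitude=38.0, t_mean_C=16.0, t_amp_C=9.0, t_peak_doy=197,
        p_annual_mm=550.0, p_concentration=0.75, wet_center_doy=15,
    ),
    # short warm season, harsh winter
    "boreal": CellSpec(
        latitude=60.0, t_mean_C=2.0, t_amp_C=16.0, t_peak_doy=197,
        p_annual_mm=550.0, p_concentration=0.4, wet_center_doy=197,
    ),
}


def preset(name: str, **overrides) -> CellSpec:
    """A named preset cell spec, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


def mixed_grid_specs(n_cells: int, seed: int = 0) -> list[CellSpec]:
    """A seeded fixture grid spanning both hemispheres and all four
    seasonality classes, warm enough in summer for every default crop.

    Cells are sampled around the presets with jittered parameters; the
    warmest month always reaches at least ~18 degC so the thermal rules
    produce workable calendars, while coldest-month temperatures sweep
    through the winter-wheat decision breakpoints (-10 and 0 degC).
    """
    rng = np.random.default_rng(seed)
    names = sorted(PRESETS)
    specs = []
    for i in range(n_cells):
        base = PRESETS[names[i % len(names)]]
        south = bool(rng.integers(0, 2))
        t_mean = base.t_mean_C + rng.uniform(-3.0, 3.0)
        t_amp = max(0.0, base.t_amp_C + rng.uniform(-2.0, 2.0))
        # keep the warm season usable for the thermal rules
        t_mean = max(t_mean, 18.5 - t_amp)
        shift = 182 if south else 0
        spec = CellSpec(
            latitude=-abs(base.latitude) if south else abs(base.latitude),
            t_mean_C=t_mean,
            t_amp_C=t_amp,
            t_peak_doy=int((base.t_peak_doy + shift - 1) % DAYS_PER_YEAR) + 1,
            p_annual_mm=base.p_annual_mm * rng.uniform(0.8, 1.2),
            p_concentration=min(1.0, max(0.0, base.p_concentration + rng.uniform(-0.1, 0.1))),
            wet_center_doy=int((base.wet_center_doy + shift - 1) % DAYS_PER_YEAR) + 1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)
    return specs
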