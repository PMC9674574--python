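"""Area-weighted evaluation of simulated crop calendars against
observations.

The headline metric is the area-weighted mean absolute error

    MAE = sum_i |S_i - O_i| * A_i / sum_i A_i

over grid cells or countries, where S_i and O_i are simulated and observed
dates (DOY) and A_i the crop-specific harvested area of unit i.  Date
differences are circular by default (min of the two ways around the
365-day year), so winter-sown calendars straddling the year boundary do
not produce spurious ~350-day errors; plain differences are available for
comparison with conventions that do not wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import DAYS_PER_YEAR

__all__ = ["DateComparison", "circular_date_diff", "mae_weighted", "country_aggregate"]


@dataclass(frozen=True)
class DateComparison:
    """One evaluation unit (grid cell or country)."""

    unit_id: str
    simulated_doy: int
    observed_doy: int
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")
        for val in (self.simulated_doy, self.observed_doy):
            if not 1 <= val <= DAYS_PER_YEAR:
                raise ValueError("dates must lie in [1, 365]")


def circular_date_diff(a: int, b: int) -> float:
    """Absolute DOY difference on the circular 365-day calendar (<= 182.5)."""
    d = abs(a - b)
    return min(d, DAYS_PER_YEAR - d)


def mae_weighted(comparisons: list[DateComparison], circular: bool = True) -> float:
    """Area-weighted mean absolute error (days) over comparison units."""
    if not comparisons:
        raise ValueError("no comparisons supplied")
    areas = np.array([c.area for c in comparisons], dtype=float)
    if areas.sum() == 0:
        raise ValueError("total area weight is zero")
    if circular:
        diffs = np.array(
            [circular_date_diff(c.simulated_doy, c.observed_doy) for c in comparisons],
            dtype=float,
        )
    else:
        diffs = np.array(
            [abs(c.simulated_doy - c.observed_doy) for c in comparisons], dtype=float
        )
    return float((diffs * areas).sum() / areas.sum())


def country_aggregate(
    cells: pd.DataFrame,
    date_col: str,
    country_col: str = "country",
    area_col: str = "area",
) -> pd.DataFrame:
    """Area-weighted mean cell date per country (rounded to integer DOY).

    Observed calendars are often reported per country even when gridded, so
    simulated cell dates are aggregated the same way before comparison.
    """
    def _wmean(group: pd.DataFrame) -> float:
        w = group[area_col].to_numpy(dtype=float)
        d = group[date_col].to_numpy(dtype=float)
        if w.sum() == 0:
            return float(np.mean(d))
        return float((d * w).sum() / w.sum())

    agg = cells.groupby(country_col).apply(_wmean, include_groups=False)
    area = cells.groupby(country_col)[area_col].sum()
    out = pd.DataFrame({date_col: agg.round().astype(int), area_col: area})
    return out.reset_index()
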