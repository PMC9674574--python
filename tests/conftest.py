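import numpy as np
import pytest

from cropcal.calendars import default_crop_params
from cropcal.climate import MONTH_MID_DOY, DAYS_PER_YEAR, MonthlyClimate


@pytest.fixture(scope="session")
def crop_params():
    return default_crop_params()


def sinusoid_mc(
    mean_C: float,
    amp_C: float,
    peak_doy: int = 197,
    precip_mm: float | np.ndarray = 60.0,
    pet_mm: float | np.ndarray = 80.0,
) -> MonthlyClimate:
    """Monthly climatology with sinusoidal temperature sampled at the
    mid-month anchors and flat (or prescribed) precipitation/PET."""
    temp = mean_C + amp_C * np.cos(
        2.0 * np.pi * (MONTH_MID_DOY - peak_doy) / DAYS_PER_YEAR
    )
    return MonthlyClimate(
        temp_C=temp,
        precip_mm=np.broadcast_to(np.asarray(precip_mm, float), (12,)).copy(),
        pet_mm=np.broadcast_to(np.asarray(pet_mm, float), (12,)).copy(),
    )


def mc_with_coldest(coldest_C: float, amp_C: float = 14.0, peak_doy: int = 197,
                    **kw) -> MonthlyClimate:
    """Sinusoidal climatology shifted so the coldest month is exactly
    *coldest_C*; used to probe the wheat-type decision breakpoints."""
    mc = sinusoid_mc(0.0, amp_C, peak_doy, **kw)
    shift = coldest_C - mc.temp_C.min()
    return MonthlyClimate(
        temp_C=mc.temp_C + shift, precip_mm=mc.precip_mm, pet_mm=mc.pet_mm
    )
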