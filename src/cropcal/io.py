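"""Tabular and gridded I/O plus run configuration.

Conventions shared by every artifact this package reads or writes:

* day-of-year fields are 1-based integers on the 365-day no-leap calendar;
* delimited tables are comma-separated with a header row;
* gridded monthly climate follows the (cell, month) dimension order, round
  trippable through an :class:`xarray.Dataset`;
* a missing maturity (crop never matured) is serialized as the sentinel -1.

Each run can stamp its outputs with a provenance header (config hash,
seeds, package version) sufficient to re-create deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .calendars import CropCalendar, Driver, WheatType
from .climate import MonthlyClimate
from .cultivars import CultivarParams

__all__ = [
    "MISSING_DOY",
    "RunConfig",
    "load_config",
    "save_config",
    "read_monthly_climate_table",
    "write_monthly_climate_table",
    "monthly_climate_to_dataset",
    "dataset_to_monthly_climate",
    "calendars_to_frame",
    "frame_to_calendars",
    "cultivars_to_frame",
    "frame_to_cultivars",
    "provenance_header",
]

MISSING_DOY = -1

_CONFIG_FIELDS = {
    "crop_params_path": None,
    "periods": ("baseline", "intermediate", "future"),
    "scenarios": ("reference", "no_adaptation", "delayed_adaptation", "timely_adaptation"),
    "seed": 0,
    "n_years": 20,
    "out_dir": "out",
    "verbosity": 1,
}


@dataclass(frozen=True)
class RunConfig:
    crop_params_path: str | None = None
    periods: tuple[str, ...] = ("baseline", "intermediate", "future")
    scenarios: tuple[str, ...] = (
        "reference",
        "no_adaptation",
        "delayed_adaptation",
        "timely_adaptation",
    )
    seed: int = 0
    n_years: int = 20
    out_dir: str = "out"
    verbosity: int = 1

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; omitted keys take the documented
    defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_FIELDS, **raw}
    for key in ("periods", "scenarios"):
        merged[key] = tuple(merged[key])
    cfg = RunConfig(**merged)
    if cfg.crop_params_path is not None and not Path(cfg.crop_params_path).exists():
        raise FileNotFoundError(cfg.crop_params_path)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["periods"] = list(data["periods"])
    data["scenarios"] = list(data["scenarios"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def provenance_header(cfg: RunConfig, version: str) -> str:
    return (
        f"# cropcal v{version} | config {cfg.digest()} | seed {cfg.seed} | "
        "DOY convention: 1-based, 365-day no-leap calendar\n"
    )


# ---------------------------------------------------------------- climate I/O

def write_monthly_climate_table(
    climates: dict[str, MonthlyClimate], path: str | Path
) -> None:
    """Write cell climatologies as a long table:
    cell_id, month, temp_C, precip_mm, pet_mm."""
    rows = []
    for cell_id, mc in climates.items():
        for m in range(12):
            rows.append(
                {
                    "cell_id": cell_id,
                    "month": m + 1,
                    "temp_C": mc.temp_C[m],
                    "precip_mm": mc.precip_mm[m],
                    "pet_mm": mc.pet_mm[m],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_monthly_climate_table(path: str | Path) -> dict[str, MonthlyClimate]:
    df = pd.read_csv(path)
    out: dict[str, MonthlyClimate] = {}
    for cell_id, group in df.groupby("cell_id", sort=False):
        group = group.sort_values("month")
        if list(group["month"]) != list(range(1, 13)):
            raise ValueError(f"cell {cell_id}: expected months 1..12")
        out[str(cell_id)] = MonthlyClimate(
            temp_C=group["temp_C"].to_numpy(),
            precip_mm=group["precip_mm"].to_numpy(),
            pet_mm=group["pet_mm"].to_numpy(),
        )
    return out


def monthly_climate_to_dataset(climates: dict[str, MonthlyClimate]) -> xr.Dataset:
    """Pack cell climatologies into an xarray Dataset with (cell, month)
    dimensions, NetCDF-convention ready."""
    cells = list(climates)
    stack = lambda attr: np.stack([getattr(climates[c], attr) for c in cells])
    return xr.Dataset(
        {
            "temp_C": (("cell", "month"), stack("temp_C")),
            "precip_mm": (("cell", "month"), stack("precip_mm")),
            "pet_mm": (("cell", "month"), stack("pet_mm")),
        },
        coords={"cell": cells, "month": np.arange(1, 13)},
        attrs={"calendar": "365_day", "doy_convention": "1-based"},
    )


def dataset_to_monthly_climate(ds: xr.Dataset) -> dict[str, MonthlyClimate]:
    out = {}
    for cell in ds["cell"].values:
        sel = ds.sel(cell=cell)
        out[str(cell)] = MonthlyClimate(
            temp_C=sel["temp_C"].values,
            precip_mm=sel["precip_mm"].values,
            pet_mm=sel["pet_mm"].values,
        )
    return out


# --------------------------------------------------------------- calendar I/O

def calendars_to_frame(
    calendars: dict[str, CropCalendar], crop: str, water_regime: str = "rainfed"
) -> pd.DataFrame:
    """One row per cell: the sowing/grain-filling/maturity DOYs plus the
    decision metadata.  Identical tables are valid for either water regime."""
    rows = []
    for cell_id, cal in calendars.items():
        rows.append(
            {
                "cell_id": cell_id,
                "crop": crop,
                "water_regime": water_regime,
                "sowing_doy": cal.sowing_doy,
                "gf_start_doy": cal.gf_start_doy,
                "maturity_doy": cal.maturity_doy if cal.maturity_doy else MISSING_DOY,
                "wheat_type": cal.wheat_type.value if cal.wheat_type else "",
                "driver": cal.driver.value,
            }
        )
    return pd.DataFrame(rows)


def frame_to_calendars(df: pd.DataFrame) -> dict[str, CropCalendar]:
    out = {}
    for _, row in df.iterrows():
        out[str(row["cell_id"])] = CropCalendar(
            sowing_doy=int(row["sowing_doy"]),
            gf_start_doy=int(row["gf_start_doy"]),
            maturity_doy=int(row["maturity_doy"]),
            wheat_type=(
                WheatType(row["wheat_type"])
                if isinstance(row["wheat_type"], str) and row["wheat_type"]
                else None
            ),
            driver=Driver(row["driver"]),
        )
    return out


def cultivars_to_frame(
    cultivars: dict[str, CultivarParams], period_label: str = ""
) -> pd.DataFrame:
    rows = [
        {
            "cell_id": cell_id,
            "crop": cv.crop,
            "period_label": period_label or cv.source_period,
            "tu_req": cv.tu_req,
            "vu_req": cv.vu_req,
        }
        for cell_id, cv in cultivars.items()
    ]
    return pd.DataFrame(rows)


def frame_to_cultivars(df: pd.DataFrame) -> dict[str, CultivarParams]:
    return {
        str(row["cell_id"]): CultivarParams(
            crop=str(row["crop"]),
            tu_req=float(row["tu_req"]),
            vu_req=float(row["vu_req"]),
            source_period=str(row.get("period_label", "")),
        )
        for _, row in df.iterrows()
    }
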