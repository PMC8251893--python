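"""Decomposition of projected emissions by proximate loss driver.

Future deforestation from each driver is assumed proportional to its
historical contribution, so a province's projection splits cleanly into
five driver components: annual area loss A1*d*p_i at the baseline and
cumulative CO2-eq from the per-driver carbon addend c_max*f_i*p_i run
through the cohort closed form. Because the model is linear in the carbon
density, driver components sum exactly to the aggregate run.

Reporting conventions: Tg CO2-eq to 1 decimal place, shares to the nearest
integer percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .emissions_core import (
    ModelConfig,
    applied_shares,
    per_driver_emissions,
    to_co2eq,
)
from .province_data import DRIVERS, Driver, DRIVER_INDEX, ProvinceRecord

__all__ = ["DriverDecomposition", "decompose", "driver_share", "decomposition_table"]


@dataclass(frozen=True)
class DriverDecomposition:
    """Per-driver annual loss (ha yr^-1) and cumulative emissions (Tg CO2-eq)."""

    province_id: str
    annual_loss_ha: tuple[float, float, float, float, float]
    cumulative_co2eq_tg: tuple[float, float, float, float, float]
    province_total_co2eq_tg: float

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.annual_loss_ha):
            raise ValueError(f"{self.province_id}: negative annual loss")
        # totals must re-add from components up to reporting rounding
        if abs(sum(self.cumulative_co2eq_tg) - self.province_total_co2eq_tg) > 0.5:
            raise ValueError(
                f"{self.province_id}: driver emissions "
                f"{sum(self.cumulative_co2eq_tg):.3f} Tg do not sum to the "
                f"province total {self.province_total_co2eq_tg:.3f} Tg"
            )


def decompose(record: ProvinceRecord, config: ModelConfig) -> DriverDecomposition:
    """Split a province's horizon emissions across the five drivers.

    Sequestration is a province-level counterfactual, not attributable to a
    driver, so the decomposition covers the emissions component only.
    """
    shares = applied_shares(record, config)
    annual = record.area_2010 * record.deforestation_rate * shares
    emitted_c = per_driver_emissions(record, config, config.horizon_years)
    tg = to_co2eq(emitted_c, config.co2_per_c)
    return DriverDecomposition(
        province_id=record.province_id,
        annual_loss_ha=tuple(float(x) for x in annual),
        cumulative_co2eq_tg=tuple(float(x) for x in tg),
        province_total_co2eq_tg=float(tg.sum()),
    )


def driver_share(decomp: DriverDecomposition, driver: Driver) -> int:
    """Driver's share of the province total, nearest integer percent."""
    total = decomp.province_total_co2eq_tg
    if total <= 0:
        raise ValueError(
            f"{decomp.province_id}: driver shares are undefined for a "
            f"zero-emissions province"
        )
    frac = decomp.cumulative_co2eq_tg[DRIVER_INDEX[driver]] / total
    return int(round(100.0 * frac))


def decomposition_table(decomps: Sequence[DriverDecomposition]) -> pd.DataFrame:
    """One row per province: annual ha loss and Tg CO2-eq per driver.

    Mirrors the layout of a per-driver emissions summary table, with share
    columns appended; Tg rounded to 1 decimal, shares to integer percent.
    """
    rows = []
    for dc in decomps:
        row: dict[str, object] = {"province_id": dc.province_id}
        for i, drv in enumerate(DRIVERS):
            row[f"annual_loss_ha_{drv.value}"] = round(dc.annual_loss_ha[i], 1)
            row[f"co2eq_tg_{drv.value}"] = round(dc.cumulative_co2eq_tg[i], 1)
        row["total_co2eq_tg"] = round(dc.province_total_co2eq_tg, 1)
        for drv in DRIVERS:
            if dc.province_total_co2eq_tg > 0:
                row[f"share_pct_{drv.value}"] = driver_share(dc, drv)
            else:
                row[f"share_pct_{drv.value}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_decomposition_csv(
    decomps: Iterable[DriverDecomposition], path: str | Path
) -> None:
    decomposition_table(list(decomps)).to_csv(path, index=False)
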