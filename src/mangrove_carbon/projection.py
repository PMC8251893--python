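"""Global projection: run every province to the horizon, rank, aggregate.

Provinces are ranked by their emissions-only totals (the quantity used for
hotspot identification); ties break lexicographically on province_id so
runs are reproducible. Both emissions-only and emissions-plus-foregone-
sequestration totals are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .emissions_core import (
    ModelConfig,
    foregone_sequestration,
    per_driver_emissions,
    to_co2eq,
)
from .province_data import ProvinceRecord

__all__ = ["GlobalProjection", "project_all", "hotspot_share", "concentration_share"]


@dataclass(frozen=True)
class GlobalProjection:
    """Ranked province totals and global sums, in Tg CO2-eq.

    ``ranking`` lists province_ids by decreasing emissions-only total;
    ``emissions_tg`` and ``with_seq_tg`` are parallel to it.
    """

    ranking: tuple[str, ...]
    emissions_tg: np.ndarray
    with_seq_tg: np.ndarray
    global_emissions_tg: float
    global_with_seq_tg: float

    def province_total(self, province_id: str, *, with_sequestration: bool = False) -> float:
        idx = self.ranking.index(province_id)
        series = self.with_seq_tg if with_sequestration else self.emissions_tg
        return float(series[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "province_id": self.ranking,
                "emissions_tg_co2eq": np.round(self.emissions_tg, 1),
                "emissions_plus_foregone_seq_tg_co2eq": np.round(self.with_seq_tg, 1),
            }
        )


def project_all(records: Sequence[ProvinceRecord], config: ModelConfig) -> GlobalProjection:
    """Project every province to the horizon via the closed forms.

    A province with zero deforestation stays in the table with total 0.
    """
    if len(records) == 0:
        raise ValueError("project_all needs at least one province")
    ids = [r.province_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate province_id in input records")
    T = config.horizon_years
    emissions = np.empty(len(records))
    with_seq = np.empty(len(records))
    for i, rec in enumerate(records):
        e_c = per_driver_emissions(rec, config, T).sum()
        s_c = (
            foregone_sequestration(rec.area_2010, rec.deforestation_rate,
                                   rec.sequestration_rate, T)
            if config.include_sequestration
            else 0.0
        )
        emissions[i] = to_co2eq(e_c, config.co2_per_c)
        with_seq[i] = to_co2eq(e_c + s_c, config.co2_per_c)
    order = sorted(range(len(records)), key=lambda i: (-emissions[i], ids[i]))
    return GlobalProjection(
        ranking=tuple(ids[i] for i in order),
        emissions_tg=emissions[order],
        with_seq_tg=with_seq[order],
        global_emissions_tg=float(emissions.sum()),
        global_with_seq_tg=float(with_seq.sum()),
    )


def concentration_share(
    totals: Sequence[float], k: int, global_total: float | None = None
) -> int:
    """Share of the global total held by the k largest totals, integer percent.

    ``global_total`` defaults to the sum of ``totals``; passing it
    explicitly supports computing the share of a published global figure
    from a subset of province totals.
    """
    arr = np.sort(np.asarray(totals, dtype=float))[::-1]
    if not 1 <= k <= arr.size:
        raise ValueError(f"k must be in [1, {arr.size}], got {k}")
    total = float(arr.sum()) if global_total is None else float(global_total)
    if total <= 0:
        raise ValueError("global total must be positive")
    return int(round(100.0 * arr[:k].sum() / total))


def hotspot_share(projection: GlobalProjection, k: int) -> int:
    """Top-k province share of global emissions-only total, integer percent."""
    return concentration_share(projection.emissions_tg, k,
                               projection.global_emissions_tg)


def write_projection_csv(projection: GlobalProjection, path: str | Path) -> None:
    projection.to_frame().to_csv(path, index=False)


def summary_text(projection: GlobalProjection, k: int = 6) -> str:
    """Plain-text block with global totals and the top-k concentration."""
    k = min(k, len(projection.ranking))
    lines = [
        f"provinces: {len(projection.ranking)}",
        f"global emissions (Tg CO2-eq): {projection.global_emissions_tg:.1f}",
        "global emissions incl. foregone sequestration (Tg CO2-eq): "
        f"{projection.global_with_seq_tg:.1f}",
        f"top-{k} share of global emissions: {hotspot_share(projection, k)}%",
        f"top-{k} provinces: " + ", ".join(projection.ranking[:k]),
    ]
    return "\n".join(lines) + "\n"
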