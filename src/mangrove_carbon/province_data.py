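"""Province-level data model for mangrove carbon accounting.

The spatial accounting unit is the marine province (top-level coastal
bioregion). Each province carries its 2010 mangrove extent, a constant
annual deforestation rate, carbon stocks (soil organic carbon to 1 m and
2 m, aboveground carbon), the proportional contribution of five proximate
loss drivers, and a per-driver emission factor (the fraction of the labile
stock emitted after conversion to that land use).

Total ecosystem carbon stock (TECS) is the sum of SOC at a chosen depth
and aboveground carbon; the default depth is 2 m, since 1-m accounting
systematically understates mangrove soil stocks.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Driver",
    "DRIVERS",
    "BIOMASS_TO_CARBON",
    "EmissionFactor",
    "ProvinceRecord",
    "RegressionFit",
    "abc_from_biomass",
    "compute_tecs",
    "validate_against_field",
    "load_province_table",
    "write_province_table",
]

#: Biomass -> carbon mass fraction for mangrove aboveground biomass.
BIOMASS_TO_CARBON = 0.48


class Driver(Enum):
    """Proximate driver of mangrove loss, in canonical order."""

    COMMODITIES = "commodities"  # conversion to agriculture/aquaculture
    EROSION = "erosion"
    CLEARING = "clearing"
    CLIMATIC_EVENT = "climatic_event"  # tropical storms, sea-level anomalies
    SETTLEMENT = "settlement"


#: Canonical driver order; every 5-vector in the package is keyed by it.
DRIVERS: tuple[Driver, ...] = tuple(Driver)
DRIVER_INDEX: dict[Driver, int] = {drv: i for i, drv in enumerate(DRIVERS)}
N_DRIVERS = len(DRIVERS)

#: Tolerance on the driver-share simplex constraint.
SHARE_TOL = 1e-9


@dataclass(frozen=True)
class EmissionFactor:
    """Fraction of a carbon stock emitted after a given land-use conversion.

    ``confidence`` follows a three-level ladder: 1 = global-average factor
    (lowest), 2 = factor from a similar region, 3 = similar region with the
    same geomorphic setting (highest).
    """

    fraction: float
    confidence: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(
                f"emission factor fraction must be in [0, 1], got {self.fraction}"
            )
        if self.confidence not in (1, 2, 3):
            raise ValueError(
                f"emission factor confidence must be 1, 2 or 3, got {self.confidence}"
            )


@dataclass(frozen=True)
class ProvinceRecord:
    """One marine province's inputs to the emissions projection.

    Units: areas in ha, rates in yr^-1 (decimal fractions), stocks in
    Mg C ha^-1, sequestration in Mg C ha^-1 yr^-1. ``soc_2m`` may be NaN
    when only 1-m soil data exist; requesting 2-m TECS then fails loudly
    rather than silently falling back.
    """

    province_id: str
    name: str
    area_2010: float
    deforestation_rate: float
    soc_1m: float
    soc_2m: float
    abc: float
    driver_shares: tuple[float, float, float, float, float]
    emission_factors: tuple[
        EmissionFactor, EmissionFactor, EmissionFactor, EmissionFactor, EmissionFactor
    ]
    sequestration_rate: float = 1.5
    #: Optional replacement for the computed TECS (e.g. field-measured
    #: stocks in a sensitivity scenario); None means derive from SOC + ABC.
    tecs_override: float | None = None

    def __post_init__(self) -> None:
        if not self.province_id:
            raise ValueError("province_id must be non-empty")
        for fld in ("area_2010", "deforestation_rate", "soc_1m", "abc",
                    "sequestration_rate"):
            val = getattr(self, fld)
            if not math.isfinite(val) or val < 0:
                raise ValueError(
                    f"province {self.province_id!r}: {fld} must be finite and "
                    f"non-negative, got {val}"
                )
        if math.isfinite(self.soc_2m) and self.soc_2m < self.soc_1m:
            raise ValueError(
                f"province {self.province_id!r}: soc_2m ({self.soc_2m}) < "
                f"soc_1m ({self.soc_1m})"
            )
        shares = self.driver_shares
        if len(shares) != N_DRIVERS:
            raise ValueError(
                f"province {self.province_id!r}: expected {N_DRIVERS} driver "
                f"shares, got {len(shares)}"
            )
        if any(s < 0 for s in shares):
            raise ValueError(
                f"province {self.province_id!r}: negative driver share"
            )
        total = sum(shares)
        all_zero = all(s == 0.0 for s in shares)
        if not all_zero and abs(total - 1.0) > SHARE_TOL:
            raise ValueError(
                f"province {self.province_id!r}: driver shares sum to "
                f"{total:.12g}, expected 1"
            )
        if all_zero and self.deforestation_rate > 0:
            raise ValueError(
                f"province {self.province_id!r}: zero driver shares with "
                f"non-zero deforestation rate"
            )
        if len(self.emission_factors) != N_DRIVERS:
            raise ValueError(
                f"province {self.province_id!r}: expected {N_DRIVERS} emission "
                f"factors, got {len(self.emission_factors)}"
            )

    @property
    def shares_array(self) -> np.ndarray:
        return np.asarray(self.driver_shares, dtype=float)

    @property
    def factors_array(self) -> np.ndarray:
        return np.asarray([ef.fraction for ef in self.emission_factors], dtype=float)

    def with_tecs_override(self, tecs: float) -> "ProvinceRecord":
        return replace(self, tecs_override=tecs)


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of field stocks on modelled stocks."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"regression needs n >= 2, got {self.n}")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def abc_from_biomass(biomass):
    """Convert aboveground biomass (Mg ha^-1) to carbon (Mg C ha^-1).

    Applies the standard mangrove biomass carbon fraction of 0.48.
    Accepts scalars or arrays.
    """
    arr = np.asarray(biomass, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"biomass must be non-negative, got {biomass}")
    out = arr * BIOMASS_TO_CARBON
    return float(out) if np.isscalar(biomass) or arr.ndim == 0 else out


def compute_tecs(record: ProvinceRecord, soc_depth: str = "2m") -> float:
    """Total ecosystem carbon stock: SOC at ``soc_depth`` plus ABC (Mg C ha^-1).

    ``soc_depth`` is ``"1m"`` or ``"2m"`` (default). A record whose 2-m SOC
    is missing (NaN) raises when 2 m is requested; there is deliberately no
    silent fallback to the 1-m stock.
    """
    if record.tecs_override is not None:
        return float(record.tecs_override)
    if soc_depth == "1m":
        soc = record.soc_1m
    elif soc_depth == "2m":
        soc = record.soc_2m
        if not math.isfinite(soc):
            raise ValueError(
                f"province {record.province_id!r}: soc_2m is missing but 2 m "
                f"TECS was requested; pass soc_depth='1m' explicitly if intended"
            )
    else:
        raise ValueError(f"soc_depth must be '1m' or '2m', got {soc_depth!r}")
    return float(soc + record.abc)


def validate_against_field(
    modelled: Sequence[float], field_values: Sequence[float]
) -> RegressionFit:
    """Regress field-measured stocks on modelled stocks (OLS).

    Used to check globally modelled TECS against field plots from provinces
    where verified measurements exist. Field stocks are the response and
    modelled stocks the predictor, so the slope reads as the factor by which
    the model under- or over-predicts reality.
    """
    x = np.asarray(modelled, dtype=float)
    y = np.asarray(field_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"modelled and field must be equal-length 1-D sequences, got "
            f"shapes {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValueError(f"need at least 2 paired stocks, got {x.size}")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


# CSV dialect ----------------------------------------------------------------

CSV_HEADER = [
    "province_id", "name", "area_ha", "deforestation_rate",
    "soc1m_mgc_ha", "soc2m_mgc_ha", "abc_mgc_ha",
    "share_commodities", "share_erosion", "share_clearing",
    "share_climatic", "share_settlement",
    "ef_commodities", "ef_erosion", "ef_clearing", "ef_climatic",
    "ef_settlement",
    "efconf_commodities", "efconf_erosion", "efconf_clearing",
    "efconf_climatic", "efconf_settlement",
    "seq_rate_mgc_ha_yr",
]

_SHARE_COLS = ["share_commodities", "share_erosion", "share_clearing",
               "share_climatic", "share_settlement"]
_EF_COLS = ["ef_commodities", "ef_erosion", "ef_clearing", "ef_climatic",
            "ef_settlement"]
_EFCONF_COLS = ["efconf_commodities", "efconf_erosion", "efconf_clearing",
                "efconf_climatic", "efconf_settlement"]


#: Fallback emission factors used when a province/driver cell is blank:
#: global-average fractions, carried at the lowest confidence level (1).
GLOBAL_MEAN_EF: dict[Driver, float] = {
    Driver.COMMODITIES: 0.80,
    Driver.EROSION: 0.65,
    Driver.CLEARING: 0.60,
    Driver.CLIMATIC_EVENT: 0.40,
    Driver.SETTLEMENT: 0.85,
}


def _parse_float(raw: str, default: float = math.nan) -> float:
    raw = raw.strip()
    return default if raw == "" else float(raw)


def load_province_table(path: str | Path) -> list[ProvinceRecord]:
    """Read a province CSV (see :data:`CSV_HEADER`) into validated records.

    Rates must be decimal fractions (0.0055, not 0.55%). Every validation
    failure is re-raised with the offending data row number (1-based,
    excluding the header) so bad rows can be located in the file.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        got = reader.fieldnames or []
        unknown = [c for c in got if c not in CSV_HEADER]
        missing = [c for c in CSV_HEADER if c not in got]
        if unknown:
            raise ValueError(f"{path}: unknown column(s) {unknown}")
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        records: list[ProvinceRecord] = []
        for rownum, row in enumerate(reader, start=1):
            try:
                factors = []
                for drv, c, cc in zip(DRIVERS, _EF_COLS, _EFCONF_COLS):
                    frac = _parse_float(row[c], default=math.nan)
                    if math.isnan(frac):
                        # blank cell: global-average factor, lowest confidence
                        factors.append(
                            EmissionFactor(GLOBAL_MEAN_EF[drv], confidence=1)
                        )
                    else:
                        factors.append(
                            EmissionFactor(
                                frac,
                                confidence=int(_parse_float(row[cc], default=1)),
                            )
                        )
                factors = tuple(factors)
                rec = ProvinceRecord(
                    province_id=row["province_id"].strip(),
                    name=row["name"].strip(),
                    area_2010=_parse_float(row["area_ha"]),
                    deforestation_rate=_parse_float(row["deforestation_rate"]),
                    soc_1m=_parse_float(row["soc1m_mgc_ha"]),
                    soc_2m=_parse_float(row["soc2m_mgc_ha"]),
                    abc=_parse_float(row["abc_mgc_ha"]),
                    driver_shares=tuple(
                        _parse_float(row[c], default=0.0) for c in _SHARE_COLS
                    ),
                    emission_factors=factors,
                    sequestration_rate=_parse_float(
                        row["seq_rate_mgc_ha_yr"], default=1.5
                    ),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {rownum}: {exc}") from exc
            records.append(rec)
    return records


def write_province_table(records: Iterable[ProvinceRecord], path: str | Path) -> None:
    """Write records in the CSV dialect read by :func:`load_province_table`.

    Uses repr-round-trip float formatting so load -> write -> load is exact.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            fmt = lambda v: repr(float(v))
            row = [
                rec.province_id, rec.name,
                fmt(rec.area_2010), fmt(rec.deforestation_rate),
                fmt(rec.soc_1m),
                "" if math.isnan(rec.soc_2m) else fmt(rec.soc_2m),
                fmt(rec.abc),
                *[fmt(s) for s in rec.driver_shares],
                *[fmt(ef.fraction) for ef in rec.emission_factors],
                *[str(int(ef.confidence)) for ef in rec.emission_factors],
                fmt(rec.sequestration_rate),
            ]
            writer.writerow(row)
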