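"""Scenario grid and formal parameter sensitivity of cumulative emissions.

Two complementary tools:

* :func:`run_grid` re-runs the global projection under alternative input
  datasets and model switches (area source, deforestation-rate source, SOC
  depth, field vs modelled stocks, erosion emission-factor scaling,
  climatic-event losses on/off) and summarises how stable the hotspot
  ranking is across scenarios (top-6 set overlap, top-6-within-top-8
  containment).

* :func:`derivative` differentiates a province's horizon total L with
  respect to each model parameter. The model is linear in initial area A1,
  labile stock c_max, the emission factors f_i and the sequestration rate s,
  so those derivatives are exact ratios (dL/dtheta = L_theta / theta). The
  deforestation rate d and release rate r enter through exponentials and are
  differentiated by central finite difference with a relative step of 1e-4.
  Elasticities theta * dL/dtheta / L make the mixed-unit derivatives
  comparable across parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emissions_core import (
    ModelConfig,
    applied_shares,
    foregone_sequestration,
    per_driver_emissions,
    province_cmax,
    to_co2eq,
)
from .projection import GlobalProjection, project_all
from .province_data import DRIVERS, Driver, DRIVER_INDEX, ProvinceRecord

__all__ = [
    "ScenarioSpec",
    "SensitivityReport",
    "GridResult",
    "run_grid",
    "derivative",
    "PARAMETERS",
]

#: Relative step for central finite differences (d and r).
FD_RELATIVE_STEP = 1e-4

#: Differentiable parameters. f_<driver> addresses one emission factor.
PARAMETERS = ("A1", "d", "c_max", "r", "s") + tuple(
    f"f_{drv.value}" for drv in DRIVERS
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the sensitivity grid.

    ``area_dataset`` / ``rate_dataset`` name per-province input variants
    ("base" = the records as loaded); ``stock_source`` is "modelled" or the
    name of a stocks variant (e.g. "field").
    """

    label: str
    area_dataset: str = "base"
    rate_dataset: str = "base"
    soc_depth: str = "2m"
    stock_source: str = "modelled"
    erosion_ef_multiplier: float = 1.0
    include_climatic: bool = True


@dataclass(frozen=True)
class SensitivityReport:
    """Derivative of the horizon total L with respect to one parameter.

    ``derivative`` is in Tg CO2-eq per unit of the parameter;
    ``elasticity`` is dimensionless and NaN (with ``elasticity_defined``
    False) for a zero-emissions province.
    """

    province_id: str
    parameter: str
    value: float
    derivative: float
    elasticity: float
    method: str  # "analytic" or "finite_difference"
    elasticity_defined: bool = True


@dataclass(frozen=True)
class GridResult:
    summary: pd.DataFrame
    projections: dict[str, GlobalProjection]
    base: GlobalProjection


def _province_total_tg(record: ProvinceRecord, config: ModelConfig) -> float:
    """Horizon total L for one province in Tg CO2-eq (emissions, plus
    foregone sequestration when configured)."""
    e_c = per_driver_emissions(record, config, config.horizon_years).sum()
    s_c = (
        foregone_sequestration(record.area_2010, record.deforestation_rate,
                               record.sequestration_rate, config.horizon_years)
        if config.include_sequestration
        else 0.0
    )
    return float(to_co2eq(e_c + s_c, config.co2_per_c))


# --- scenario grid ----------------------------------------------------------


def _lookup_variant(
    variants: Mapping[str, Mapping[str, Mapping[str, float]]] | None,
    kind: str,
    tag: str,
    label: str,
) -> Mapping[str, float]:
    table = (variants or {}).get(kind, {})
    if tag not in table:
        raise ValueError(
            f"scenario {label!r} references unknown {kind} dataset {tag!r}"
        )
    return table[tag]


def _apply_scenario(
    records: Sequence[ProvinceRecord],
    base_config: ModelConfig,
    sc: ScenarioSpec,
    variants: Mapping | None,
) -> tuple[list[ProvinceRecord], ModelConfig]:
    config = replace(
        base_config,
        soc_depth=sc.soc_depth,
        erosion_ef_multiplier=sc.erosion_ef_multiplier,
        include_climatic_driver=sc.include_climatic,
    )
    out: list[ProvinceRecord] = []
    area_map = (
        _lookup_variant(variants, "area", sc.area_dataset, sc.label)
        if sc.area_dataset != "base" else None
    )
    rate_map = (
        _lookup_variant(variants, "rate", sc.rate_dataset, sc.label)
        if sc.rate_dataset != "base" else None
    )
    stock_map = (
        _lookup_variant(variants, "stocks", sc.stock_source, sc.label)
        if sc.stock_source != "modelled" else None
    )
    for rec in records:
        changes: dict[str, object] = {}
        for attr, mapping, kind in (
            ("area_2010", area_map, sc.area_dataset),
            ("deforestation_rate", rate_map, sc.rate_dataset),
        ):
            if mapping is not None:
                if rec.province_id not in mapping:
                    raise ValueError(
                        f"scenario {sc.label!r}: dataset {kind!r} has no value "
                        f"for province {rec.province_id!r}"
                    )
                changes[attr] = float(mapping[rec.province_id])
        if stock_map is not None:
            if rec.province_id not in stock_map:
                raise ValueError(
                    f"scenario {sc.label!r}: stocks {sc.stock_source!r} has no "
                    f"value for province {rec.province_id!r}"
                )
            changes["tecs_override"] = float(stock_map[rec.province_id])
        out.append(dataclasses.replace(rec, **changes) if changes else rec)
    return out, config


def run_grid(
    records: Sequence[ProvinceRecord],
    base_config: ModelConfig,
    scenarios: Sequence[ScenarioSpec],
    variants: Mapping | None = None,
) -> GridResult:
    """Run the global projection once per scenario.

    The summary table reports each scenario's global totals plus two
    rank-stability metrics against the base run: the size of the top-6 set
    intersection, and how many of the base top-6 fall inside the scenario's
    top-8 (hotspots may reshuffle locally while staying near the top).
    """
    labels = [sc.label for sc in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique within a grid")
    base = project_all(records, base_config)
    k6 = min(6, len(base.ranking))
    k8 = min(8, len(base.ranking))
    base_top6 = set(base.ranking[:k6])
    rows = []
    projections: dict[str, GlobalProjection] = {}
    for sc in scenarios:
        sc_records, sc_config = _apply_scenario(records, base_config, sc, variants)
        proj = project_all(sc_records, sc_config)
        projections[sc.label] = proj
        top6 = set(proj.ranking[:k6])
        top8 = set(proj.ranking[:k8])
        rows.append(
            {
                "label": sc.label,
                "global_emissions_tg": round(proj.global_emissions_tg, 1),
                "global_with_seq_tg": round(proj.global_with_seq_tg, 1),
                "top6_overlap_with_base": len(top6 & base_top6),
                "base_top6_in_top8": len(base_top6 & top8),
            }
        )
    return GridResult(summary=pd.DataFrame(rows), projections=projections, base=base)


# --- parameter derivatives --------------------------------------------------


def _report(record, parameter, value, deriv, L, method) -> SensitivityReport:
    defined = L != 0.0
    elasticity = value * deriv / L if defined else math.nan
    return SensitivityReport(
        province_id=record.province_id,
        parameter=parameter,
        value=float(value),
        derivative=float(deriv),
        elasticity=float(elasticity),
        method=method,
        elasticity_defined=defined,
    )


def derivative(
    record: ProvinceRecord, config: ModelConfig, parameter: str
) -> SensitivityReport:
    """dL/d(parameter) for one province, in Tg CO2-eq per parameter unit.

    ``parameter`` is one of :data:`PARAMETERS`. Linear parameters (A1,
    c_max, f_i, s) get exact analytic derivatives; d and r get central
    finite differences with relative step 1e-4 (r is the common release
    rate: all per-driver rates are perturbed together and the derivative is
    taken at their mean).
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; use one of {PARAMETERS}")
    L = _province_total_tg(record, config)
    T = config.horizon_years

    if parameter == "A1":
        # whole model is proportional to initial area
        a1 = record.area_2010
        if a1 <= 0:
            raise ValueError("A1 derivative requires positive initial area")
        return _report(record, parameter, a1, L / a1, L, "analytic")

    if parameter == "c_max":
        c_max = province_cmax(record, config)
        if c_max <= 0:
            raise ValueError("c_max derivative requires positive labile stock")
        e_tg = to_co2eq(
            per_driver_emissions(record, config, T).sum(), config.co2_per_c
        )
        return _report(record, parameter, c_max, e_tg / c_max, L, "analytic")

    if parameter == "s":
        s = record.sequestration_rate
        if config.include_sequestration and s > 0:
            s_tg = to_co2eq(
                foregone_sequestration(record.area_2010,
                                       record.deforestation_rate, s, T),
                config.co2_per_c,
            )
            deriv = s_tg / s
        elif config.include_sequestration:
            # derivative at s = 0 from the closed form's linear s-dependence
            if record.deforestation_rate > 0:
                d = record.deforestation_rate
                deriv = to_co2eq(
                    record.area_2010 * (T + math.expm1(-d * T) / d),
                    config.co2_per_c,
                )
            else:
                deriv = 0.0
        else:
            deriv = 0.0
        return _report(record, parameter, s, deriv, L, "analytic")

    if parameter.startswith("f_"):
        drv = Driver(parameter[2:])
        i = DRIVER_INDEX[drv]
        f_i = record.emission_factors[i].fraction
        mult = config.erosion_ef_multiplier if drv is Driver.EROSION else 1.0
        if mult * f_i > 1.0:
            deriv = 0.0  # factor clipped at 1: locally insensitive
        else:
            e_i = to_co2eq(
                per_driver_emissions(record, config, T)[i], config.co2_per_c
            )
            if f_i > 0:
                deriv = e_i / f_i
            else:
                from .emissions_core import cumulative_emissions
                p_i = applied_shares(record, config)[i]
                c_max = province_cmax(record, config)
                deriv = to_co2eq(
                    cumulative_emissions(
                        record.area_2010, record.deforestation_rate,
                        c_max * mult * p_i, config.release_rates[i], T,
                    ),
                    config.co2_per_c,
                )
        return _report(record, parameter, f_i, deriv, L, "analytic")

    if parameter == "d":
        d = record.deforestation_rate
        if d <= 0:
            raise ValueError("d derivative requires a positive deforestation rate")
        h = FD_RELATIVE_STEP * d
        lo = _province_total_tg(replace(record, deforestation_rate=d - h), config)
        hi = _province_total_tg(replace(record, deforestation_rate=d + h), config)
        return _report(record, parameter, d, (hi - lo) / (2 * h), L,
                       "finite_difference")

    # parameter == "r": common multiplicative shift of all release rates
    rates = config.release_rates
    r_mean = float(rates.mean())
    eps = FD_RELATIVE_STEP
    cfg_hi = replace(config, emission_release_rate=tuple(rates * (1 + eps)))
    cfg_lo = replace(config, emission_release_rate=tuple(rates * (1 - eps)))
    hi = _province_total_tg(record, cfg_hi)
    lo = _province_total_tg(record, cfg_lo)
    deriv = (hi - lo) / (2 * eps * r_mean)
    return _report(record, "r", r_mean, deriv, L, "finite_difference")


def derivative_table(
    records: Sequence[ProvinceRecord],
    config: ModelConfig,
    parameters: Sequence[str] = ("A1", "d", "c_max", "r", "s"),
) -> pd.DataFrame:
    """Derivatives and elasticities for every province and parameter."""
    rows = []
    for rec in records:
        for param in parameters:
            try:
                rep = derivative(rec, config, param)
            except ValueError:
                continue  # e.g. d = 0 provinces have no d-derivative
            rows.append(dataclasses.asdict(rep))
    return pd.DataFrame(rows)
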