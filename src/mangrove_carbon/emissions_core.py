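"""Cohort model of carbon emissions after mangrove deforestation.

The projection treats each province as a stock of mangrove area A(t)
shrinking at a constant proportional deforestation rate d,

    dA/dt = -A d            =>  A(t) = A1 exp(-d t),

so the area deforested during [y, y+dy) — a *cohort* — is A1 d exp(-d y) dy.
Each cohort carries an effective labile carbon density c (Mg C ha^-1) and
releases it exponentially at rate r after loss: a cohort deforested at time
y has emitted the fraction 1 - exp(-r (t - y)) of its stock by time t.
Cumulative emissions up to a horizon T are the convolution

    E(T) = \\int_0^T A1 d e^{-d y} c (1 - e^{-r (T - y)}) dy,

which has the closed form (r != d)

    E(T) = A1 c [ 1 - e^{-dT} - d (e^{-dT} - e^{-rT}) / (r - d) ],

with the analytic limit E(T) = A1 c [1 - e^{-dT} - d T e^{-dT}] at r = d.
E is bounded by A1 c and approaches it as T grows: everything that is ever
deforested eventually emits its labile stock, so the release rate r shifts
emissions in time without changing the eventual total.

Foregone sequestration is the counterfactual gap between soil carbon
accrual without deforestation (s A1 per year) and with it (s A(t)):

    S(T) = s A1 T - s A1 (1 - e^{-dT}) / d,   S -> 0 as d -> 0.

The effective carbon density per province weights the maximum labile stock
c_max (TECS) by the proportional driver mix p_i and per-driver emission
factors f_i:  c = c_max * sum_i f_i p_i, with per-driver addends
c_i = c_max f_i p_i used for attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .province_data import (
    DRIVERS,
    Driver,
    DRIVER_INDEX,
    N_DRIVERS,
    ProvinceRecord,
    SHARE_TOL,
    compute_tecs,
)

__all__ = [
    "DEFAULT_RELEASE_RATE",
    "CO2_PER_C",
    "ModelConfig",
    "EmissionTrajectory",
    "area_remaining",
    "effective_carbon",
    "cumulative_emissions",
    "foregone_sequestration",
    "to_co2eq",
    "trajectory",
    "applied_factors",
    "applied_shares",
    "province_cmax",
]

#: Default emission-release rate: a 10-year half-life for the labile stock
#: of a deforested hectare (decadal, not instantaneous, emissions).
DEFAULT_RELEASE_RATE = math.log(2) / 10.0

#: CO2:C molecular mass ratio.
CO2_PER_C = 44.0 / 12.0

#: Relative r-vs-d proximity below which the analytic r = d limit is used.
_LIMIT_TOL = 1e-9


@dataclass(frozen=True)
class ModelConfig:
    """Projection settings shared by every province run.

    ``emission_release_rate`` is a per-driver 5-vector in canonical driver
    order (yr^-1); the default applies one global decadal rate to every
    driver. ``erosion_ef_multiplier`` scales the erosion emission factor
    (0.5 models partial compensation of erosion losses by accretion);
    ``include_climatic_driver=False`` removes climatic-event losses without
    reassigning them to other drivers.
    """

    horizon_years: float = 90.0  # 2010-2100
    baseline_year: int = 2010
    emission_release_rate: tuple[float, ...] = (DEFAULT_RELEASE_RATE,) * N_DRIVERS
    co2_per_c: float = CO2_PER_C
    include_sequestration: bool = True
    erosion_ef_multiplier: float = 1.0
    include_climatic_driver: bool = True
    soc_depth: str = "2m"

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError(f"horizon_years must be > 0, got {self.horizon_years}")
        if len(self.emission_release_rate) != N_DRIVERS:
            raise ValueError(
                f"emission_release_rate needs {N_DRIVERS} entries, got "
                f"{len(self.emission_release_rate)}"
            )
        if any(r <= 0 for r in self.emission_release_rate):
            raise ValueError("all emission release rates must be > 0")
        if self.co2_per_c <= 0:
            raise ValueError(f"co2_per_c must be > 0, got {self.co2_per_c}")
        if self.erosion_ef_multiplier < 0:
            raise ValueError("erosion_ef_multiplier must be >= 0")
        if self.soc_depth not in ("1m", "2m"):
            raise ValueError(f"soc_depth must be '1m' or '2m', got {self.soc_depth!r}")

    @property
    def release_rates(self) -> np.ndarray:
        return np.asarray(self.emission_release_rate, dtype=float)


@dataclass(frozen=True)
class EmissionTrajectory:
    """Time series of one province's projection on a uniform annual-style grid.

    Carbon series are in Mg C; ``cumulative_co2eq`` is in Tg CO2-eq and
    includes foregone sequestration only when the run was configured to.
    """

    province_id: str
    times: np.ndarray
    area: np.ndarray
    cumulative_emitted_c: np.ndarray
    cumulative_foregone_seq_c: np.ndarray
    cumulative_co2eq: np.ndarray


def area_remaining(a1: float, d: float, t):
    """Remaining mangrove area A1 exp(-d t) in ha; ``t`` may be an array."""
    if a1 < 0:
        raise ValueError(f"initial area must be non-negative, got {a1}")
    if d < 0:
        raise ValueError(f"deforestation rate must be non-negative, got {d}")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be non-negative")
    out = a1 * np.exp(-d * tt)
    return float(out) if tt.ndim == 0 else out


def effective_carbon(
    c_max: float,
    factors,
    shares,
    *,
    check_simplex: bool = True,
) -> tuple[float, np.ndarray]:
    """Driver-weighted emittable carbon density (Mg C ha^-1).

    Returns ``(c, addends)`` where ``c = c_max * sum_i f_i p_i`` and
    ``addends[i] = c_max * f_i * p_i`` is driver i's contribution, so
    attribution and the aggregate run are consistent by construction.

    ``check_simplex=False`` admits share vectors that no longer lie on the
    simplex because a scenario zeroed a driver without renormalising.
    """
    f = np.asarray(factors, dtype=float)
    p = np.asarray(shares, dtype=float)
    if f.shape != (N_DRIVERS,) or p.shape != (N_DRIVERS,):
        raise ValueError(f"factors and shares must be length-{N_DRIVERS} vectors")
    if np.any((f < 0) | (f > 1)):
        raise ValueError(f"emission factors must lie in [0, 1], got {f}")
    if np.any(p < 0):
        raise ValueError(f"driver shares must be non-negative, got {p}")
    if check_simplex:
        total = float(p.sum())
        if not (abs(total - 1.0) <= SHARE_TOL or total == 0.0):
            raise ValueError(f"driver shares must sum to 1 or 0, got {total:.12g}")
    addends = c_max * f * p
    return float(addends.sum()), addends


def _release_fraction(d: float, r: float, t):
    """G(t) = E(t) / (A1 c): fraction of the eventual stock emitted by t.

    Uses expm1 for the (r - d) cancellation so the expression stays accurate
    arbitrarily close to the r = d degeneracy, with an exact limit branch
    below the switchover.
    """
    tt = np.asarray(t, dtype=float)
    if d == 0.0:
        out = np.zeros_like(tt)
        return float(out) if tt.ndim == 0 else out
    edt = np.exp(-d * tt)
    if abs(r - d) < _LIMIT_TOL * max(r, d):
        out = 1.0 - edt - d * tt * edt
    else:
        # e^{-dt} - e^{-rt} cancels when (r-d)t is small; there use the
        # equivalent -e^{-dt} expm1(-(r-d)t), which is exact in that regime
        # and cannot overflow because its argument is tiny.
        x = (r - d) * tt
        small = np.abs(x) < 1e-3
        diff = np.where(
            small,
            edt * -np.expm1(-np.where(small, x, 0.0)),
            edt - np.exp(-r * tt),
        )
        out = 1.0 - edt - d * diff / (r - d)
    return float(out) if tt.ndim == 0 else out


def cumulative_emissions(a1: float, d: float, c: float, r: float, t) -> float:
    """Cumulative emitted carbon E(t) in Mg C (closed form).

    ``a1`` ha of initial extent lost at rate ``d`` yr^-1, each lost hectare
    releasing ``c`` Mg C exponentially at rate ``r`` yr^-1. ``t`` may be an
    array of horizons. ``r`` must be positive: a non-positive release rate
    would mean deforested carbon never emits and the model degenerates.
    """
    if min(a1, d, c) < 0:
        raise ValueError(
            f"a1, d and c must be non-negative, got ({a1}, {d}, {c})"
        )
    if r <= 0:
        raise ValueError(f"release rate r must be > 0, got {r}")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("horizon must be non-negative")
    out = a1 * c * _release_fraction(d, r, tt)
    return float(out) if tt.ndim == 0 else out


def foregone_sequestration(a1: float, d: float, s: float, t) -> float:
    """Foregone soil-carbon sequestration S(t) in Mg C (closed form).

    The no-deforestation counterfactual accrues s*A1 per year; the actual
    trajectory accrues s*A(t). Their cumulative difference is
    s A1 (t - (1 - e^{-dt}) / d), 0 when d = 0.
    """
    if min(a1, d, s) < 0:
        raise ValueError(f"a1, d and s must be non-negative, got ({a1}, {d}, {s})")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("horizon must be non-negative")
    if d == 0.0:
        out = np.zeros_like(tt)
    else:
        out = s * a1 * (tt + np.expm1(-d * tt) / d)
    return float(out) if tt.ndim == 0 else out


def to_co2eq(mass_c, co2_per_c: float = CO2_PER_C):
    """Convert Mg C to Tg CO2-eq (mass ratio 44/12 by default)."""
    arr = np.asarray(mass_c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("carbon mass must be non-negative")
    out = arr * co2_per_c / 1e6
    return float(out) if arr.ndim == 0 else out


def applied_factors(record: ProvinceRecord, config: ModelConfig) -> np.ndarray:
    """Emission-factor vector after scenario adjustments (erosion multiplier)."""
    f = record.factors_array
    f = f.copy()
    f[DRIVER_INDEX[Driver.EROSION]] *= config.erosion_ef_multiplier
    return np.clip(f, 0.0, 1.0)


def applied_shares(record: ProvinceRecord, config: ModelConfig) -> np.ndarray:
    """Driver-share vector after scenario adjustments.

    Removing climatic-event losses zeroes that share *without* renormalising
    the rest: the scenario removes that loss, it does not reassign it.
    """
    p = record.shares_array.copy()
    if not config.include_climatic_driver:
        p[DRIVER_INDEX[Driver.CLIMATIC_EVENT]] = 0.0
    return p


def province_cmax(record: ProvinceRecord, config: ModelConfig) -> float:
    """Maximum labile carbon density c_max for a province (TECS, Mg C ha^-1)."""
    return compute_tecs(record, soc_depth=config.soc_depth)


def per_driver_emissions(
    record: ProvinceRecord, config: ModelConfig, t
) -> np.ndarray:
    """Per-driver cumulative emitted carbon at horizon(s) ``t`` (Mg C).

    Shape (5,) for scalar t, (5, len(t)) for array t. Each driver's cohort
    flux shares the province deforestation rate d; its carbon addend is
    c_max f_i p_i and it may carry its own release rate.
    """
    c_max = province_cmax(record, config)
    _, addends = effective_carbon(
        c_max,
        applied_factors(record, config),
        applied_shares(record, config),
        check_simplex=False,
    )
    rates = config.release_rates
    rows = [
        cumulative_emissions(record.area_2010, record.deforestation_rate,
                             addends[i], rates[i], t)
        for i in range(N_DRIVERS)
    ]
    return np.asarray(rows)


def trajectory(
    record: ProvinceRecord, config: ModelConfig, n_steps: int | None = None
) -> EmissionTrajectory:
    """Evaluate the closed forms on a uniform time grid from 0 to the horizon.

    ``n_steps`` defaults to one step per year (91 points for the 90-year
    horizon). The grid is for inspection and plotting; end-of-horizon
    numbers always come from the closed forms, which the final grid point
    equals exactly.
    """
    if n_steps is None:
        n_steps = int(round(config.horizon_years))
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    times = np.linspace(0.0, config.horizon_years, n_steps + 1)
    area = area_remaining(record.area_2010, record.deforestation_rate, times)
    emitted = per_driver_emissions(record, config, times).sum(axis=0)
    if config.include_sequestration:
        foregone = foregone_sequestration(
            record.area_2010, record.deforestation_rate,
            record.sequestration_rate, times,
        )
    else:
        foregone = np.zeros_like(times)
    co2eq = to_co2eq(emitted + foregone, config.co2_per_c)
    return EmissionTrajectory(
        province_id=record.province_id,
        times=times,
        area=area,
        cumulative_emitted_c=emitted,
        cumulative_foregone_seq_c=foregone,
        cumulative_co2eq=co2eq,
    )
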