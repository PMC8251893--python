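# Methods

## Model structure and assumptions

The unit of accounting is the marine province. Within a province the model
assumes (i) a constant proportional deforestation rate `d`, so area decays
exponentially from the 2010 extent `A₁`; (ii) a constant per-hectare
effective labile carbon density `c`; (iii) first-order release of that
carbon after loss at rate `r`; and (iv) future losses distributed across
the five proximate drivers (conversion to commodities, erosion, clearing,
extreme climatic events, conversion to settlements — this canonical order
is fixed everywhere a 5-vector appears) in proportion to each driver's
historical share of loss.

Cumulative emissions are the cohort convolution

    E(T) = ∫₀ᵀ A₁ d e^(−dy) c (1 − e^(−r(T−y))) dy,

evaluated in closed form (`emissions_core.cumulative_emissions`). The
integrand's printed antecedents admit more than one reading; the cohort
convolution is the interpretation consistent with release over decades
rather than in the year of loss, and it is the one implemented. Three
consequences are load-bearing and tested as invariants:

* **Conservation** — `0 ≤ E(T) ≤ A₁c`, with `E → A₁c` as `T → ∞`. The
  release rate only redistributes emissions in time; horizon totals at
  T = 90 yr are already insensitive to `r` (∂E/∂r → 0 as T grows).
* **Linearity** — `E` is proportional to `A₁` and to `c`. Hence the exact
  per-driver decomposition via the addends `cᵢ = c_max fᵢ pᵢ` and the exact
  derivative ratios used in the sensitivity module.
* **Degeneracy handling** — at `r = d` the closed form has a removable
  singularity; an analytic limit branch engages below a relative gap of
  1e−9, and the general branch uses `expm1` for the cancelling difference
  so accuracy holds arbitrarily close to the switchover (verified against
  adaptive quadrature to 1e−8 relative).

Foregone sequestration is the counterfactual difference between soil-carbon
accrual without and with deforestation, at a constant rate `s` applied from
the moment of loss, on gross lost area (no accretion offset):
`S(T) = sA₁T − sA₁(1 − e^(−dT))/d`. It is a province-level counterfactual
and is not attributed to drivers.

## Parameters, units, defaults

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `horizon_years` | projection horizon | yr | 90 | 2010 baseline to end of century |
| `emission_release_rate` | per-driver release rate `r` | yr⁻¹ | ln 2 / 10 | a 10-year half-life encodes decadal release; no empirical per-driver rates exist, so one global default, configurable per driver |
| `co2_per_c` | CO₂:C conversion | — | 44/12 | molecular mass ratio |
| `sequestration_rate` | soil accrual `s` | Mg C ha⁻¹ yr⁻¹ | 1.5 | global mean soil sequestration for mangroves |
| `soc_depth` | SOC depth for TECS | — | 2 m | 1-m accounting understates mangrove soil stocks; 1 m retained for sensitivity runs |
| `erosion_ef_multiplier` | scales erosion `f` | — | 1.0 | 0.5 models partial compensation of eroded carbon by accretion/reburial |
| `include_climatic_driver` | climatic losses on/off | — | on | the off-scenario zeroes the climatic share *without renormalising*: the loss is removed, not reassigned |

Aboveground carbon is biomass × 0.48. TECS defaults to SOC(2 m) + ABC and
never silently falls back to 1 m when the 2-m stock is missing. A blank
emission factor falls back to a package global-average value flagged at the
lowest confidence level (1) of the three-level ladder (1 = global average,
2 = similar region, 3 = similar region and geomorphic setting).

## Sensitivity analysis

`sensitivity.run_grid` re-runs the projection under alternative inputs
(area/rate dataset variants supplied as per-province mappings, SOC depth,
field-vs-modelled stocks via a TECS override, erosion-factor scaling,
climatic on/off) and reports rank stability as the top-6 set overlap with
the base run plus containment of the base top-6 within each scenario's
top-8 — hotspots can reshuffle locally while remaining near the top.

`sensitivity.derivative` returns ∂L/∂θ (Tg CO₂-eq per parameter unit) and
the elasticity θ·∂L/∂θ/L. The model is linear in `A₁`, `c_max`, each `fᵢ`
and `s`, so those derivatives are exact ratios (method `analytic`); `d` and
`r` enter through exponentials and are differentiated by central finite
difference with a *relative* step of 1e−4 — relative, because parameter
magnitudes span six orders. For `r` the derivative is taken with respect to
a common multiplicative shift of all per-driver rates, evaluated at their
mean. A zero-emissions province has an undefined elasticity, flagged
explicitly rather than returned as 0.

## Synthetic province generator

`synthetic_data.generate` emulates the *province-level statistical
structure* of the global input datasets so the whole pipeline runs with no
download: log-normal areas (μ = 10.2, σ = 2.0 on ln ha, chosen so that at
37 provinces the median largest province is ≈1.8 × 10⁶ ha and the ten
largest hold ≈88 % of extent — individual seeds vary widely, as heavy
tails do); truncated-normal loss rates (across-province mean 0.09 %/yr,
SD 0.12 %/yr, truncated to [0, 0.55 %/yr], with 2 of 37 provinces assigned
zero loss and the nonzero mean inflated to compensate); truncated-normal
stocks matching the reported means and ranges (SOC 2 m 646.7 [408.6, 975.9];
SOC 1 m 331.3 [207.4, 497.8]; ABC 101.2 [9.9, 466.0] Mg C ha⁻¹, the 1-m
draw capped at the 2-m draw); and Dirichlet driver shares with expectation
proportional to the global per-driver loss totals (219,392 / 92,787 /
39,595 / 41,525 / 10,529 ha) and concentration 2.0, small enough that
single-driver-dominant provinces occur. Truncated-normal locations are
solved numerically so the post-truncation mean equals the target. Emission
factors are uniform within per-driver ranges ordered by how completely each
conversion releases the stock. One seeded generator drives all draws.

What the generator does *not* emulate: spatial covariance between
neighbouring provinces, correlation between area and loss rate or between
stocks and drivers, temporal change in rates or driver mixes, and
measurement error in any input. Passing tests therefore demonstrate the
pipeline's correctness and calibration recovery, not predictive accuracy
for the real coastline.

`synthetic_data.fixture_table1` reconstructs six records from published
per-driver annual losses and cumulative emissions. Because no consistent
(A₁, d, stocks, factors) tuple is published per province, the fixture fixes
`d` (published where available; 0.20 %/yr for Andaman and 0.15 %/yr for the
North Brazil Shelf, within the ≥0.1 %/yr range characteristic of the top
emitters), sets `A₁ = (total annual loss)/d`, and solves each per-driver
carbon addend so the closed form reproduces the printed cell at T = 90.
The resulting stock and factor fields are synthetic reconstructions, not
measurements — the Andaman cells imply effective carbon densities well
above typical field TECS.

## Numerical and reporting choices

* Closed forms are authoritative for horizon totals; the trajectory grid
  (default 91 annual points) is for inspection and equals the closed forms
  at its final point by construction.
* Reporting rounds Tg CO₂-eq to 1 decimal and shares to integer percent;
  all internal arithmetic is double precision, rounding happens only at the
  report boundary.
* Ranking ties break lexicographically on province_id; zero-deforestation
  provinces stay listed with total 0.
* CSV round-trips are exact: floats are written with repr so
  load → write → load is the identity.
* Timestamps are confined to the run manifest, so result files from
  identical commands are byte-identical.

## Problem sizes

The test suite and the acceptance script use the six-province published
fixture, 37-province synthetic tables for pipeline-level checks, and
1000–2000-province tables for distributional recovery; property tests draw
~60–150 randomized parameter sets per invariant. These sizes make the full
suite run in seconds while leaving every code path exercised.

## Known limitations

Constant `d`, `c`, `r` and `s` per province; no CH₄/N₂O accounting, no
tidal carbon-export partitioning, no area gain from sea-level rise or
landward migration, no temporal evolution of driver mixes, and no
uncertainty propagation over emission-factor confidence levels (confidence
is carried as metadata only). The two global published totals
(2391 / 3392 Tg CO₂-eq) depend on the full 37-province observational input
table, which is not redistributable here; they appear only as printed
inputs to the concentration-share check, never as recomputed outputs.
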