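import dataclasses

import numpy as np
import pytest
import sympy

from mangrove_carbon.emissions_core import DEFAULT_RELEASE_RATE, ModelConfig
from mangrove_carbon.projection import project_all
from mangrove_carbon.sensitivity import (
    FD_RELATIVE_STEP,
    PARAMETERS,
    ScenarioSpec,
    derivative,
    derivative_table,
    run_grid,
    _province_total_tg,
)

from .conftest import make_province


class TestRunGrid:
    def test_identity_scenario_equals_base(self, synthetic37, default_config):
        grid = run_grid(synthetic37, default_config, [ScenarioSpec(label="base")])
        proj = grid.projections["base"]
        assert proj.ranking == grid.base.ranking
        assert proj.global_emissions_tg == pytest.approx(
            grid.base.global_emissions_tg, rel=1e-12
        )
        row = grid.summary.iloc[0]
        assert row["top6_overlap_with_base"] == 6
        assert row["base_top6_in_top8"] == 6

    def test_erosion_half_on_erosion_only_province(self, default_config):
        rec = make_province(shares=(0, 1, 0, 0, 0))
        cfg = dataclasses.replace(default_config, include_sequestration=False)
        grid = run_grid(
            [rec], cfg, [ScenarioSpec(label="half", erosion_ef_multiplier=0.5)]
        )
        assert grid.projections["half"].global_emissions_tg == pytest.approx(
            0.5 * grid.base.global_emissions_tg, rel=1e-12
        )

    def test_soc_depth_scenario_uses_1m_stock(self, province, default_config):
        grid = run_grid(
            [province], default_config, [ScenarioSpec(label="1m", soc_depth="1m")]
        )
        assert (
            grid.projections["1m"].global_emissions_tg
            < grid.base.global_emissions_tg
        )

    def test_rate_variant_and_top6_overlap_by_hand(self, default_config):
        # eight provinces with strictly decreasing totals via area
        recs = [
            make_province(province_id=f"P{i}", area=1e5 * (9 - i)) for i in range(8)
        ]
        # alternative rates silence the three largest provinces; the survivors
        # P3..P7 fill the top-5 and the zero-total ties order lexicographically
        alt = {
            r.province_id: (0.0 if r.province_id in {"P0", "P1", "P2"} else 0.004)
            for r in recs
        }
        grid = run_grid(
            recs, default_config,
            [ScenarioSpec(label="alt", rate_dataset="rates_2016")],
            variants={"rate": {"rates_2016": alt}},
        )
        assert grid.projections["alt"].ranking == (
            "P3", "P4", "P5", "P6", "P7", "P0", "P1", "P2",
        )
        # hand enumeration: base top-6 {P0..P5}, alt top-6 {P3..P7, P0}
        # -> intersection {P0, P3, P4, P5} = 4
        assert grid.summary.iloc[0]["top6_overlap_with_base"] == 4

    def test_missing_variant_named_in_error(self, province, default_config):
        with pytest.raises(ValueError, match="nosuch"):
            run_grid(
                [province], default_config,
                [ScenarioSpec(label="x", area_dataset="nosuch")],
            )

    def test_field_stock_source_overrides_tecs(self, province, default_config):
        field_tecs = 2.0 * (province.soc_2m + province.abc)
        grid = run_grid(
            [province], default_config,
            [ScenarioSpec(label="field", stock_source="field")],
            variants={"stocks": {"field": {province.province_id: field_tecs}}},
        )
        got = grid.projections["field"].global_emissions_tg
        assert got == pytest.approx(2.0 * grid.base.global_emissions_tg, rel=1e-12)

    def test_duplicate_labels_rejected(self, province, default_config):
        with pytest.raises(ValueError, match="unique"):
            run_grid(
                [province], default_config,
                [ScenarioSpec(label="a"), ScenarioSpec(label="a")],
            )


def fd(fun, theta, rel=FD_RELATIVE_STEP):
    h = rel * theta
    return (fun(theta + h) - fun(theta - h)) / (2 * h)


class TestDerivative:
    def test_linear_parameters_are_exact_ratios(self, province, default_config):
        L = _province_total_tg(province, default_config)
        rep_a1 = derivative(province, default_config, "A1")
        assert rep_a1.method == "analytic"
        assert rep_a1.derivative == pytest.approx(L / province.area_2010, rel=1e-12)
        assert rep_a1.elasticity == pytest.approx(1.0, rel=1e-12)

        rep_c = derivative(province, default_config, "c_max")
        cfg_ns = dataclasses.replace(default_config, include_sequestration=False)
        e_only = _province_total_tg(province, cfg_ns)
        c_max = province.soc_2m + province.abc
        assert rep_c.derivative == pytest.approx(e_only / c_max, rel=1e-12)

    def test_linear_analytic_agrees_with_finite_difference(
        self, province, default_config
    ):
        """Dual route: the exact linear derivatives vs a numeric probe."""
        rep = derivative(province, default_config, "A1")
        numeric = fd(
            lambda a: _province_total_tg(
                dataclasses.replace(province, area_2010=a), default_config
            ),
            province.area_2010,
        )
        assert rep.derivative == pytest.approx(numeric, rel=1e-6)

        rep_s = derivative(province, default_config, "s")
        numeric_s = fd(
            lambda s: _province_total_tg(
                dataclasses.replace(province, sequestration_rate=s), default_config
            ),
            province.sequestration_rate,
        )
        assert rep_s.derivative == pytest.approx(numeric_s, rel=1e-6)

        rep_f = derivative(province, default_config, "f_commodities")
        f0 = province.emission_factors[0].fraction
        numeric_f = fd(
            lambda f: _province_total_tg(
                dataclasses.replace(
                    province,
                    emission_factors=(
                        dataclasses.replace(province.emission_factors[0], fraction=f),
                    )
                    + province.emission_factors[1:],
                ),
                default_config,
            ),
            f0,
        )
        assert rep_f.derivative == pytest.approx(numeric_f, rel=1e-6)

    def test_loss_rate_derivative_matches_symbolic_oracle(self, default_config):
        """Central finite difference vs sympy differentiation of the closed form."""
        rec = make_province(shares=(1, 0, 0, 0, 0), factors=(0.8, 0, 0, 0, 0),
                            rate=0.01, seq=0.0)
        cfg = dataclasses.replace(default_config, include_sequestration=False)
        rep = derivative(rec, cfg, "d")
        assert rep.method == "finite_difference"

        a1, c = rec.area_2010, 0.8 * (rec.soc_2m + rec.abc)
        r, T = DEFAULT_RELEASE_RATE, cfg.horizon_years
        d = sympy.symbols("d", positive=True)
        E = a1 * c * (
            1 - sympy.exp(-d * T)
            - d * (sympy.exp(-d * T) - sympy.exp(-r * T)) / (r - d)
        )
        L = E * cfg.co2_per_c / 1e6
        symbolic = float(sympy.diff(L, d).subs(d, rec.deforestation_rate))
        assert rep.derivative == pytest.approx(symbolic, rel=1e-6)
        assert rep.derivative > 0  # more loss, more emissions

    def test_release_rate_derivative_matches_symbolic_oracle(self, default_config):
        rec = make_province(shares=(1, 0, 0, 0, 0), factors=(0.8, 0, 0, 0, 0),
                            rate=0.01, seq=0.0)
        cfg = dataclasses.replace(default_config, include_sequestration=False)
        rep = derivative(rec, cfg, "r")

        a1, c = rec.area_2010, 0.8 * (rec.soc_2m + rec.abc)
        d_val, T = rec.deforestation_rate, cfg.horizon_years
        r = sympy.symbols("r", positive=True)
        E = a1 * c * (
            1 - sympy.exp(-d_val * T)
            - d_val * (sympy.exp(-d_val * T) - sympy.exp(-r * T)) / (r - d_val)
        )
        L = E * cfg.co2_per_c / 1e6
        symbolic = float(sympy.diff(L, r).subs(r, DEFAULT_RELEASE_RATE))
        assert rep.derivative == pytest.approx(symbolic, rel=1e-6)

    def test_release_rate_only_matters_in_the_short_term(self, province):
        """dL/dr > 0 but vanishes as the horizon grows: the release rate
        shifts emissions in time without changing the eventual total."""
        derivs = []
        for T in (90.0, 400.0, 2000.0):
            cfg = ModelConfig(horizon_years=T, include_sequestration=False)
            rep = derivative(province, cfg, "r")
            assert rep.derivative > 0
            derivs.append(rep.derivative)
        assert derivs == sorted(derivs, reverse=True)
        assert derivs[-1] < 1e-3 * derivs[0]

    def test_zero_emission_province_flags_undefined_elasticity(self, default_config):
        rec = make_province(rate=0.0, shares=(0.0,) * 5, seq=0.0)
        rep = derivative(rec, default_config, "A1")
        assert not rep.elasticity_defined
        assert np.isnan(rep.elasticity)

    def test_unknown_parameter_rejected(self, province, default_config):
        with pytest.raises(ValueError, match="unknown parameter"):
            derivative(province, default_config, "q")


def test_derivative_table_covers_provinces_and_parameters(
    synthetic37, default_config
):
    df = derivative_table(synthetic37[:5], default_config)
    assert set(df.columns) >= {"province_id", "parameter", "derivative", "elasticity"}
    assert set(df.parameter) <= set(PARAMETERS)
    # d-rows exist only for deforesting provinces
    for pid in df.province_id.unique():
        rec = next(r for r in synthetic37 if r.province_id == pid)
        has_d = "d" in set(df[df.province_id == pid].parameter)
        assert has_d == (rec.deforestation_rate > 0)
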