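import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pm25burden import (
    AGE_BINS,
    DECADES,
    GriddedField,
    GridSpec,
    IERCoefficients,
    adjust_baseline_mortality,
    age_disaggregate,
    attributable_deaths,
    crude_rate,
    decade_mortality,
    generate_baseline_fields,
    generate_baseline_mortality,
    generate_scenario_drivers,
    ier_relative_risk,
    project_gdp,
)
from pm25burden.grid import zone_ids
from pm25burden.health import AGE_SPECIFIC_DISEASES, DISEASES


from conftest import make_coeffs


class TestIER:
    def test_counterfactual_and_below_give_unit_risk(self):
        coeffs = make_coeffs()
        assert ier_relative_risk(5.8, coeffs, "COPD") == 1.0
        assert ier_relative_risk(2.0, coeffs, "COPD") == 1.0
        assert ier_relative_risk(0.0, coeffs, "COPD") == 1.0

    def test_saturates_at_one_plus_alpha(self):
        coeffs = make_coeffs(alpha=0.5, gamma=0.1, delta=0.8)
        assert ier_relative_risk(1e9, coeffs, "LC") == pytest.approx(1.5, rel=1e-9)

    def test_closed_form_spot_value(self):
        coeffs = make_coeffs(alpha=1.0, gamma=0.07, delta=0.6)
        expected = 1.0 + 1.0 * (1.0 - math.exp(-0.07 * (35.0 - 5.8) ** 0.6))
        rr = ier_relative_risk(35.0, coeffs, "COPD")
        assert rr == pytest.approx(expected, rel=1e-12)
        assert rr == pytest.approx(1.411, abs=5e-4)

    def test_age_bin_required_for_age_specific_diseases(self):
        coeffs = make_coeffs()
        with pytest.raises(ValueError, match="age"):
            ier_relative_risk(30.0, coeffs, "IHD")
        assert ier_relative_risk(30.0, coeffs, "IHD", "40-44") > 1.0

    @given(
        alpha=st.floats(0.01, 3.0), gamma=st.floats(1e-4, 0.5),
        delta=st.floats(0.1, 1.5),
        c=st.floats(0.0, 300.0), dc=st.floats(0.0, 100.0),
    )
    def test_monotone_and_bounded(self, alpha, gamma, delta, c, dc):
        coeffs = make_coeffs(alpha, gamma, delta)
        r1 = ier_relative_risk(c, coeffs, "COPD")
        r2 = ier_relative_risk(c + dc, coeffs, "COPD")
        assert 1.0 <= r1 <= 1.0 + alpha + 1e-12
        assert r2 >= r1 - 1e-12

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            make_coeffs(alpha=-0.1)
        with pytest.raises(ValueError):
            make_coeffs(gamma=0.0)

    def test_default_table_loads_and_is_age_resolved(self):
        coeffs = IERCoefficients.default()
        assert coeffs.counterfactual == 5.8
        # IHD risk coefficients decline with age in the shipped set
        young = coeffs.triple("IHD", "25-29")[0]
        old = coeffs.triple("IHD", "80+")[0]
        assert young > old
        frame = coeffs.to_frame()
        again = IERCoefficients.from_frame(frame)
        assert again.triples == coeffs.triples


class TestAttributableDeaths:
    def test_unit_risk_gives_zero(self):
        assert attributable_deaths(1.0, 0.01, 1e6) == 0.0

    def test_hand_computed_value(self):
        assert attributable_deaths(2.0, 0.01, 100_000) == pytest.approx(500.0)

    def test_linear_in_population(self):
        one = attributable_deaths(1.7, 0.003, 1e5)
        two = attributable_deaths(1.7, 0.003, 2e5)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_risk_below_one_rejected(self):
        with pytest.raises(ValueError):
            attributable_deaths(0.9, 0.01, 1e5)

    @given(rr=st.floats(1.0, 50.0))
    def test_attributable_fraction_bounded(self, rr):
        af = (rr - 1.0) / rr
        assert 0.0 <= af < 1.0
        assert attributable_deaths(rr, 1.0, 1.0) == pytest.approx(af)


class TestDrivers:
    def test_age_disaggregation_conserves_total(self, config_factory):
        drv = generate_scenario_drivers(config_factory(), "ssp2")
        decade = DECADES[3]
        bins = age_disaggregate(drv, decade)
        total = sum(b.values for b in bins.values())
        np.testing.assert_allclose(total, drv.population[decade].values, rtol=1e-9)

    def test_bad_fractions_rejected(self, config_factory):
        drv = generate_scenario_drivers(config_factory(), "ssp2")
        drv.age_fractions.iloc[0, 0] += 0.02
        with pytest.raises(ValueError, match="sum"):
            age_disaggregate(drv, DECADES[0])

    @pytest.mark.parametrize(
        "iiasa,oecd,ref,base,expected",
        [(10.0, 10.0, 10.0, 100.0, 100.0),  # g = 1
         (12.0, 8.0, 10.0, 100.0, 100.0),   # averaging the two trajectories
         (30.0, 30.0, 10.0, 100.0, 300.0)], # 3x growth
    )
    def test_gdp_growth_examples(self, config_factory, iiasa, oecd, ref, base, expected):
        drv = generate_scenario_drivers(config_factory(), "ssp1")
        decade = DECADES[0]
        drv.gdp_ppp.loc[decade, "iiasa"] = iiasa
        drv.gdp_ppp.loc[decade, "oecd"] = oecd
        drv.gdp_ppp_ref = ref
        assert project_gdp(drv, decade, base) == pytest.approx(expected)


class TestBaselineMortalityAdjustment:
    def test_lc_constant_at_any_gdp(self, config_factory):
        table = generate_baseline_mortality(config_factory())
        gdps = table.table[table.table["disease"] == "LC"]["zone_gdp"].to_numpy()
        y0 = adjust_baseline_mortality(table, gdps, "LC")
        y1 = adjust_baseline_mortality(table, gdps * 25.0, "LC")
        np.testing.assert_allclose(y0, y1, rtol=1e-12)

    def test_anchored_at_baseline_gdp(self, config_factory):
        table = generate_baseline_mortality(config_factory())
        for disease in DISEASES:
            sub = table.table[table.table["disease"] == disease].sort_values("zone")
            y = adjust_baseline_mortality(table, sub["zone_gdp"].to_numpy(), disease)
            np.testing.assert_allclose(y, sub["rate"].to_numpy(), rtol=1e-12)

    def test_power_law_scale_invariance(self, config_factory):
        table = generate_baseline_mortality(config_factory())
        sub = table.table[table.table["disease"] == "COPD"].sort_values("zone")
        g = sub["zone_gdp"].to_numpy()
        b = sub["b"].to_numpy()
        ratio1 = adjust_baseline_mortality(table, 2 * g, "COPD") / adjust_baseline_mortality(table, g, "COPD")
        ratio2 = adjust_baseline_mortality(table, 6 * g, "COPD") / adjust_baseline_mortality(table, 3 * g, "COPD")
        np.testing.assert_allclose(ratio1, 2.0 ** (-b), rtol=1e-12)
        np.testing.assert_allclose(ratio1, ratio2, rtol=1e-12)

    def test_se_shift_moves_rate_monotonically(self, config_factory):
        table = generate_baseline_mortality(config_factory())
        g = 3.0 * table.table[table.table["disease"] == "IHD"]["zone_gdp"].to_numpy()
        lo = adjust_baseline_mortality(table, g, "IHD", shift=-1)
        mid = adjust_baseline_mortality(table, g, "IHD", shift=0)
        hi = adjust_baseline_mortality(table, g, "IHD", shift=+1)
        assert (lo <= mid).all() and (mid <= hi).all()


class TestDecadeMortality:
    def _study(self, config_factory, **cfg_kw):
        cfg = config_factory(**cfg_kw)
        base = generate_baseline_fields(cfg)
        drv = generate_scenario_drivers(cfg, "ssp2")
        table = generate_baseline_mortality(cfg)
        return cfg, base, drv, table, make_coeffs()

    def test_counterfactual_exposure_gives_zero_burden(self, config_factory):
        cfg, base, drv, table, coeffs = self._study(config_factory)
        flat = base.pm25.copy_with(np.full(cfg.grid.shape, coeffs.counterfactual))
        res = decade_mortality(flat, drv, table, coeffs, DECADES[0])
        assert res.total == 0.0

    def test_brute_force_triple_loop_oracle(self, config_factory):
        """Vectorised national burden equals an explicit per-cell, per-age,
        per-disease loop written straight from the closed-form relations."""
        grid = GridSpec(20.0, 23.0, 75.0, 78.0, 0.5)  # 6 x 6
        cfg, base, drv, table, coeffs = self._study(config_factory, grid=grid)
        decade = DECADES[2]
        res = decade_mortality(base.pm25.copy_with(base.pm25.values), drv, table, coeffs, decade)

        zmap = zone_ids(grid, base.pm25.mask, table.zones_k)
        growth = drv.gdp_growth(decade)
        fr = drv.age_fractions.loc[decade]
        expected = 0.0
        for i in range(grid.nlat):
            for j in range(grid.nlon):
                if not base.pm25.mask[i, j]:
                    continue
                c = base.pm25.values[i, j]
                pop = drv.population[decade].values[i, j]
                for disease in DISEASES:
                    row = table.coefficients(int(zmap[i, j]), disease)
                    y = row["a"] * (row["zone_gdp"] * growth) ** (-row["b"])
                    if disease in AGE_SPECIFIC_DISEASES:
                        for age_bin in AGE_BINS:
                            a, g, d = coeffs.triple(disease, age_bin)
                            dc = max(c - coeffs.counterfactual, 0.0)
                            rr = 1 + a * (1 - math.exp(-g * dc**d))
                            expected += y * (rr - 1) / rr * pop * fr[age_bin]
                    else:
                        a, g, d = coeffs.triple(disease)
                        dc = max(c - coeffs.counterfactual, 0.0)
                        rr = 1 + a * (1 - math.exp(-g * dc**d))
                        expected += y * (rr - 1) / rr * pop
        assert res.total == pytest.approx(expected, rel=1e-9)

    def test_single_cell_hand_oracle(self, config_factory):
        grid = GridSpec(20.0, 20.5, 75.0, 75.5, 0.5)
        cfg, base, drv, table, coeffs = self._study(config_factory, grid=grid)
        decade = DECADES[0]
        res = decade_mortality(base.pm25, drv, table, coeffs, decade)
        assert res.grid_total.values.shape == (1, 1)
        assert res.total == pytest.approx(float(res.grid_total.values.sum()), rel=1e-12)
        assert res.total > 0
        assert set(res.by_disease) == set(DISEASES)
        assert sum(res.by_disease.values()) == pytest.approx(res.total, rel=1e-12)

    def test_partition_invariance(self, config_factory):
        """National burden is the sum of any spatial partition's burdens."""
        cfg, base, drv, table, coeffs = self._study(config_factory)
        decade = DECADES[1]
        res = decade_mortality(base.pm25, drv, table, coeffs, decade)
        west = res.grid_total.values[:, : cfg.grid.nlon // 2].sum()
        east = res.grid_total.values[:, cfg.grid.nlon // 2 :].sum()
        assert west + east == pytest.approx(res.total, rel=1e-12)

    def test_bands_collapse_without_uncertainty(self, config_factory):
        coeff = {k: (v[0], v[1], 0.0, 0.0) for k, v in
                 {"COPD": (0.0012, 0.45), "IHD": (0.0022, 0.35),
                  "stroke": (0.0011, 0.40), "LC": (0.00015, 0.0)}.items()}
        cfg, base, drv, table, coeffs = self._study(config_factory, mortality_coeff=coeff)
        zero_sigma = base.pm25.copy_with(np.zeros(cfg.grid.shape))
        res = decade_mortality(base.pm25, drv, table, coeffs, DECADES[0],
                               exposure_sigma=zero_sigma)
        assert res.bands["low"] == res.bands["central"] == res.bands["high"]

    def test_band_width_grows_with_exposure_sigma(self, config_factory):
        cfg, base, drv, table, coeffs = self._study(config_factory)
        s1 = base.pm25.copy_with(np.full(cfg.grid.shape, 2.0))
        s2 = base.pm25.copy_with(np.full(cfg.grid.shape, 4.0))
        r1 = decade_mortality(base.pm25, drv, table, coeffs, DECADES[0], exposure_sigma=s1)
        r2 = decade_mortality(base.pm25, drv, table, coeffs, DECADES[0], exposure_sigma=s2)
        assert (r2.bands["high"] - r2.bands["low"]) >= (r1.bands["high"] - r1.bands["low"])

    def test_joint_band_contains_exposure_only_band(self, config_factory):
        cfg, base, drv, table, coeffs = self._study(config_factory)
        sigma = base.pm25.copy_with(np.full(cfg.grid.shape, 3.0))
        joint = decade_mortality(base.pm25, drv, table, coeffs, DECADES[0], exposure_sigma=sigma)
        coeff0 = {k: (v[0], v[1], 0.0, 0.0) for k, v in
                  {"COPD": (0.0012, 0.45), "IHD": (0.0022, 0.35),
                   "stroke": (0.0011, 0.40), "LC": (0.00015, 0.0)}.items()}
        cfg2, base2, drv2, table2, _ = self._study(config_factory, mortality_coeff=coeff0)
        expo_only = decade_mortality(base2.pm25, drv2, table2, coeffs, DECADES[0],
                                     exposure_sigma=sigma)
        assert joint.bands["low"] <= expo_only.bands["low"] + 1e-9
        assert joint.bands["high"] >= expo_only.bands["high"] - 1e-9

    def test_quadrature_mode_orders_bands(self, config_factory):
        cfg, base, drv, table, coeffs = self._study(config_factory)
        sigma = base.pm25.copy_with(np.full(cfg.grid.shape, 3.0))
        res = decade_mortality(base.pm25, drv, table, coeffs, DECADES[0],
                               exposure_sigma=sigma, uncertainty="quadrature")
        assert res.bands["low"] < res.total < res.bands["high"]


class TestCrudeRate:
    def test_arithmetic(self, config_factory):
        cfg = config_factory()
        base = generate_baseline_fields(cfg)
        drv = generate_scenario_drivers(cfg, "ssp1")
        table = generate_baseline_mortality(cfg)
        res = decade_mortality(base.pm25, drv, table, make_coeffs(), DECADES[0])
        pop = drv.national_population(DECADES[0])
        assert crude_rate(res, drv, DECADES[0]) == pytest.approx(1e5 * res.total / pop)

    def test_invariant_under_uniform_population_scaling(self, config_factory):
        cfg = config_factory()
        base = generate_baseline_fields(cfg)
        table = generate_baseline_mortality(cfg)
        coeffs = make_coeffs()
        drv = generate_scenario_drivers(cfg, "ssp1")
        decade = DECADES[0]
        r1 = decade_mortality(base.pm25, drv, table, coeffs, decade)
        rate1 = crude_rate(r1, drv, decade)
        scaled = drv.population[decade].copy_with(drv.population[decade].values * 2.0)
        drv.population[decade] = scaled
        r2 = decade_mortality(base.pm25, drv, table, coeffs, decade)
        rate2 = crude_rate(r2, drv, decade)
        assert rate1 == pytest.approx(rate2, rel=1e-12)
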