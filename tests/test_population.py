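"""Cohort dynamics, survival schedules and predicted observations."""

import numpy as np
import pytest

from pwsasa.data import FixedConstants
from pwsasa.population import (InfeasibleParametersError, half_year_survival,
                               predict_acoustic, predict_age_comps,
                               predict_eggs, predict_milt, predict_observations,
                               project_abundance, purse_seine_catch_numbers,
                               selectivity, spring_removals)

from conftest import toy_data, toy_grid, toy_params


class TestSelectivity:
    def test_midpoint_is_half(self):
        assert selectivity(3.78, 3.78, 2.27) == pytest.approx(0.5)

    def test_age4_at_reference_parameters(self):
        # 1/(1 + exp(-2.27 * 0.22)) evaluated by hand
        assert selectivity(4, 3.78, 2.27) == pytest.approx(0.6223, abs=5e-4)

    def test_knife_edge_limit(self):
        assert selectivity(4.0, 3.78, 500.0) == pytest.approx(1.0)
        assert selectivity(3.5, 3.78, 500.0) == pytest.approx(0.0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            selectivity(4, 3.78, 0.0)


class TestCatchOps:
    def test_zero_yield_zero_catch(self):
        assert purse_seine_catch_numbers(0.0, np.array([1.0]),
                                         np.array([100.0])) == 0.0

    def test_single_age_unit_case(self):
        assert purse_seine_catch_numbers(100.0, np.array([1.0]),
                                         np.array([100.0])) == pytest.approx(1.0)

    def test_two_age_mean_weight(self):
        got = purse_seine_catch_numbers(200.0, np.array([0.5, 0.5]),
                                        np.array([80.0, 120.0]))
        assert got == pytest.approx(2.0)

    def test_zero_weight_with_yield_errors(self):
        with pytest.raises(InfeasibleParametersError):
            purse_seine_catch_numbers(10.0, np.array([1.0]), np.array([0.0]))

    def test_spring_removals_arithmetic(self):
        got = spring_removals(2.0, np.array([0.5]), np.array([1.0]),
                              np.array([4.0]), rho_k=0.75)
        assert got[0] == pytest.approx(5.0)   # 0.5*2 + 1 + 0.75*4

    def test_spring_removals_no_pound_mortality(self):
        got = spring_removals(2.0, np.array([0.5]), np.array([1.0]),
                              np.array([4.0]), rho_k=0.0)
        assert got[0] == pytest.approx(2.0)


class TestHalfYearSurvival:
    def test_background_rate(self, scenario):
        s = half_year_survival(1985, 5, scenario.params)
        assert s == pytest.approx(np.exp(-0.125), abs=1e-12)

    def test_zero_disease_index_equals_background(self, scenario):
        d1 = {y: 0.0 for y in range(1994, 2013)}
        d2 = {y: 0.0 for y in range(1994, 2013)}
        s = half_year_survival(2008, 3, scenario.params, d1, d2)
        assert s == pytest.approx(np.exp(-0.125), abs=1e-12)

    def test_1992_halves_differ(self, scenario):
        p = scenario.params
        first = half_year_survival(1992, 4, p, half="first")
        second = half_year_survival(1992, 4, p, half="second")
        assert first == pytest.approx(np.exp(-0.125))
        assert second == pytest.approx(np.exp(-0.5 * (0.25 + p.mu1_1993)))

    def test_plus_group_constant_when_age8_constant(self, scenario):
        """If the age-8 rate is unchanged, the ratio form leaves 9+ unchanged."""
        p = scenario.params
        d1 = {y: 0.0 for y in range(1994, 2013)}
        d2 = {y: 0.123 for y in range(1994, 2013)}
        s_a = half_year_survival(2000, 9, p, d1, d2)
        s_b = half_year_survival(2001, 9, p, d1, d2)
        assert s_a == pytest.approx(s_b, rel=1e-12)

    def test_matches_kernel_survival_grids(self, scenario, truth):
        grid = scenario.grid
        d1 = {int(y): scenario.d1[i] for i, y in enumerate(grid.years)}
        d2 = {int(y): scenario.d2[i] for i, y in enumerate(grid.years)}
        for iy, year in enumerate(grid.years):
            for ia, age in enumerate(grid.ages):
                for half, arr in (("first", truth.state.S_first),
                                  ("second", truth.state.S_second)):
                    expected = half_year_survival(int(year), int(age),
                                                  scenario.params, d1, d2,
                                                  half=half)
                    assert arr[iy, ia] == pytest.approx(expected, rel=1e-10), \
                        (year, age, half)


class TestProjectAbundance:
    def test_zero_catch_conservation(self):
        """With no catches or disease, cohorts decay at exp(-M) exactly."""
        grid = toy_grid(n_years=3)
        data = toy_data(grid)
        params = toy_params(grid, eta=[np.log(100.0)] * 3, eta4=0.1, eta5=0.1)
        state = project_abundance(params, data)
        assert state.N[1, 1] == pytest.approx(100.0 * np.exp(-0.25), rel=1e-12)
        # age-4 1981 survivors into the plus group, plus plus-group survivors
        expected_plus = (100.0 * np.exp(-0.25)) * np.exp(-0.25) \
            + np.exp(0.1) * (np.exp(-0.25) + np.exp(-0.9)) * np.exp(-0.9)
        assert state.N[2, 2] == pytest.approx(expected_plus, rel=1e-10)

    def test_catch_removing_all_fish_is_feasible_boundary(self):
        grid = toy_grid(n_years=3)
        gill = np.zeros((3, 3))
        gill[0, 0] = 100.0                # exactly the 1980 age-3 abundance
        data = toy_data(grid, gillnet=gill)
        state = project_abundance(toy_params(grid), data)
        assert state.N[1, 1] == pytest.approx(0.0, abs=1e-9)
        assert state.N[1, 1] >= 0.0

    def test_excess_catch_is_infeasible(self):
        grid = toy_grid(n_years=3)
        gill = np.zeros((3, 3))
        gill[0, 1] = np.exp(4.0) + 1.0
        data = toy_data(grid, gillnet=gill)
        with pytest.raises(InfeasibleParametersError):
            project_abundance(toy_params(grid), data)

    def test_determinism(self, scenario, truth):
        a = project_abundance(scenario.params, truth.data, scenario.constants)
        b = project_abundance(scenario.params, truth.data, scenario.constants)
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(a.Btilde, b.Btilde)

    def test_monotonicity_in_catches(self, truth, scenario):
        """Raising any catch entry weakly lowers all downstream abundance."""
        import copy
        bumped = copy.deepcopy(truth.data)
        bumped.gillnet_caa[5, 2] += 1.0       # 1985, age 5
        base = project_abundance(scenario.params, truth.data, scenario.constants)
        alt = project_abundance(scenario.params, bumped, scenario.constants)
        assert np.all(alt.N <= base.N + 1e-12)
        assert alt.N[6, 3] < base.N[6, 3]

    def test_plus_group_bookkeeping(self):
        """With zero catch, the plus group gains exactly the age-8 survivors
        plus its own survivors."""
        grid = toy_grid(n_years=5, n_ages=7)
        data = toy_data(grid)
        params = toy_params(grid, eta=[np.log(50.0)] * 5, eta4=3.0, eta5=2.0)
        st = project_abundance(params, data)
        m9 = np.exp(-params.mu9plus)
        for iy in range(4):
            expected = st.N[iy, 5] * np.exp(-0.25) + st.N[iy, 6] * m9
            assert st.N[iy + 1, 6] == pytest.approx(expected, rel=1e-12)

    def test_biomass_identity(self, truth):
        state = truth.state
        np.testing.assert_allclose(
            state.B, (state.N * truth.data.weight).sum(axis=1), rtol=1e-12)
        assert np.all(state.Ntilde <= state.maturity * state.N + 1e-9)


class TestPredictions:
    def test_unbiased_survey_case(self):
        h1, h2 = predict_acoustic(np.array([100.0]), 0.0, np.log(2.0))
        assert h1[0] == pytest.approx(100.0)
        assert h2[0] == pytest.approx(200.0)

    def test_low_biased_survey(self):
        h1, _ = predict_acoustic(np.array([100.0]), -0.34, 0.0)
        assert h1[0] == pytest.approx(71.177, abs=5e-3)

    def test_comp_hand_example(self):
        th1, _ = predict_age_comps(np.array([10.0, 30.0]),
                                   np.array([0.5, 1.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(th1, [5 / 35, 30 / 35], rtol=1e-12)

    def test_uniform_numbers_uniform_comps(self):
        th1, thsp = predict_age_comps(np.ones(4), np.ones(4), np.ones(4))
        np.testing.assert_allclose(th1, 0.25)
        np.testing.assert_allclose(thsp, 0.25)

    def test_immature_age_has_zero_spawn_share(self):
        _, thsp = predict_age_comps(np.array([10.0, 30.0]),
                                    np.array([1.0, 1.0]), np.array([0.0, 1.0]))
        assert thsp[0] == 0.0

    def test_egg_unit_bookkeeping(self):
        # 0.5 M females x 20,000 eggs = 1e10 eggs = 0.01 trillion
        e = predict_eggs(np.array([1.0]), np.array([20000.0]), 0.5)
        assert e == pytest.approx(0.01, rel=1e-12)

    def test_egg_linearity(self):
        n = np.array([2.0, 3.0])
        f = np.array([15000.0, 25000.0])
        assert predict_eggs(2 * n, f, 0.5) == pytest.approx(
            2 * predict_eggs(n, f, 0.5), rel=1e-12)

    def test_milt_all_female_is_zero(self):
        assert predict_milt(np.array([1000.0]), np.array([1.0]), 5.0)[0] == 0.0

    def test_milt_unit_case(self):
        qT = np.log(322.58)
        got = predict_milt(np.array([2 * 322.58]), np.array([0.5]), qT)
        assert got[0] == pytest.approx(1.0, rel=1e-12)

    def test_predicted_comp_rows_normalised(self, scenario, truth):
        pred = predict_observations(scenario.params, truth.data,
                                    scenario.constants, truth.state)
        np.testing.assert_allclose(pred.Theta1hat.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(pred.ThetaSphat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pred.Ehat[truth.data.masks["eggs"]] > 0)
        assert np.all(pred.That > 0)
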