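import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwsasa.data import AgeGrid, AssessmentData, FixedConstants
from pwsasa.objective import EffectiveSampleSizes
from pwsasa.params import ParameterVector
from pwsasa.simulate import (default_scenario, simulate_observations,
                             simulate_truth)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def truth(scenario):
    return simulate_truth(scenario)


@pytest.fixture(scope="session")
def obs_data(truth):
    return simulate_observations(truth, seed=2)


@pytest.fixture(scope="session")
def flat_ess(scenario):
    ny = scenario.grid.n_years
    return EffectiveSampleSizes(seine=np.full(ny, 150.0),
                                spawn=np.full(ny, 150.0))


@pytest.fixture(scope="session")
def small_chain(obs_data, scenario, flat_ess):
    """A quick desk-scale posterior fit shared by management/retro tests."""
    from pwsasa.sampler import fit_assessment
    return fit_assessment(obs_data, scenario.constants, flat_ess,
                          n_iter=30_000, burn_frac=0.5, thin=50, seed=11)


def toy_grid(n_years=3, n_ages=3):
    return AgeGrid(first_age=3, n_ages=n_ages, first_year=1980,
                   last_year=1980 + n_years - 1)


def toy_data(grid=None, gillnet=None, pound=None, foodbait=None,
             seine_yield=None, weight=None, prop_female=None):
    """Small hand-specified dataset for exercising the dynamics directly."""
    grid = grid or toy_grid()
    ny, na = grid.n_years, grid.n_ages
    zeros = np.zeros((ny, na))
    w = weight if weight is not None else np.full((ny, na), 100.0)
    pf = prop_female if prop_female is not None else np.full(ny, 0.5)
    comp = np.full((ny, na), 1.0 / na)
    return AssessmentData(
        grid=grid,
        gillnet_caa=gillnet if gillnet is not None else zeros.copy(),
        pound_caa=pound if pound is not None else zeros.copy(),
        foodbait_caa=foodbait if foodbait is not None else zeros.copy(),
        seine_comp=comp.copy(), spawn_comp=comp.copy(),
        weight=w, fecundity=np.full((ny, na), 20000.0),
        vhsv_index=np.zeros(ny), ichthyo_index=np.zeros(ny),
        prop_female=pf,
        seine_yield=seine_yield if seine_yield is not None else np.zeros(ny),
        eggs=np.full(ny, 1.0), egg_cv=np.full(ny, 0.2),
        adfg_acoustic=np.full(ny, 1.0), pwssc_acoustic=np.full(ny, 1.0),
        pwssc_cv=np.full(ny, 0.2), milt=np.full(ny, 10.0))


def toy_params(grid, eta=None, eta4=4.0, eta5=3.0, **overrides):
    base = dict(mu9plus=0.9, beta1=50.0, beta2_1=1.0, beta2_2=0.5,
                mu1_1993=0.6, mu2_1993=0.6, alpha_v=3.8, beta_v=2.3,
                q1=-0.3, sigma_h1=0.3, q2=-0.3, sigma_h2b=0.3, qT=5.5,
                sigma_t=0.3, nu3=0.4, rhoM_1_4=0.8, rhoM_2_3=0.5)
    base.update(overrides)
    if eta is None:
        eta = np.full(grid.n_years, np.log(100.0))
    return ParameterVector(eta=np.asarray(eta, dtype=float),
                           eta_1980_age4=eta4, eta_1980_age5=eta5, **base)


@pytest.fixture
def constants():
    return FixedConstants()
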