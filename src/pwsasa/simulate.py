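"""Operating model and observation simulator for download-free testing.

The generator forward-simulates the same cohort dynamics the assessment
fits, constructs fleet catches from target exploitation fractions, and then
draws observations with the assessment's assumed error structure:
multinomial age compositions and lognormal survey indices (with per-year
survey CVs plus additional error where the likelihood assumes them).

The default scenario encodes realistic Prince William Sound-style study
conditions: an early-1980s build-up, a sharp 1992-93 collapse driven by the
estimated extra mortality, disease-prevalence covariates from 1994 on, and
fleet activity and survey masks mirroring the historical record (seine 13
years, gillnet 15, pound 16, food/bait 17, eggs 10, ADF&G acoustics 5,
PWSSC acoustics 20, milt 33).  Disease indices are covariates, not random:
they are scenario inputs, back-solved so the implied age-block mortality
follows the historical pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AgeGrid, AssessmentData, FixedConstants
from .objective import EffectiveSampleSizes
from .params import ParameterVector
from .population import (PopulationState, PredictedObservations,
                         half_year_survival, predict_observations,
                         project_abundance, selectivity)

__all__ = [
    "SimulationScenario",
    "SimulationTruth",
    "default_scenario",
    "default_true_parameters",
    "simulate_truth",
    "simulate_observations",
    "recovery_experiment",
    "IDENTIFIABLE_EXCLUDE",
]

# True age-3 recruitment by year (millions), 1980-2012: a realistic herring
# trajectory with strong 1983/1987/1991 cohorts and post-collapse failures.
_TRUE_RECRUITMENT = np.array([
    225.21, 118.78, 161.48, 447.91, 373.56, 119.70, 142.15, 1237.93, 136.76,
    28.43, 29.67, 844.99, 62.41, 135.11, 18.25, 94.46, 76.91, 142.02, 69.83,
    6.08, 22.41, 10.27, 210.28, 39.97, 19.03, 26.15, 16.74, 102.28, 94.69,
    28.11, 53.48, 9.23, 77.84])

# Target total non-fishery M by age block; the disease indices are solved
# from these so the scenario reproduces a realistic mortality history.
_M_AGE34 = np.array([0.25] * 12 + [0.93, 0.93, 1.09, 0.37, 0.25, 0.33, 0.73,
                                   0.26, 0.25, 0.26, 0.37, 0.26, 0.26, 0.26,
                                   0.26, 0.25, 0.25, 0.25, 0.27, 0.25, 0.25])
_M_AGE58 = np.array([0.25] * 12 + [0.94, 0.94, 0.32, 0.36, 0.36, 0.35, 0.39,
                                   0.36, 0.36, 0.44, 0.40, 0.54, 0.40, 0.40,
                                   0.40, 0.38, 0.33, 0.34, 0.30, 0.32, 0.36])

# Target exploitation fraction of total numbers by year (fisheries closed
# 1994-95 and from 2000 on; token food/bait- or pound-only access 1989/1999).
_EXPLOITATION = np.array([0.12, 0.21, 0.14, 0.05, 0.09, 0.08, 0.13, 0.07,
                          0.08, 0.004, 0.10, 0.17, 0.22, 0.07, 0.0, 0.0,
                          0.02, 0.18, 0.19, 0.002] + [0.0] * 13)

_SEINE_YEARS = set(range(1980, 1989)) | {1990, 1991, 1992, 1997}
_GILLNET_YEARS = _SEINE_YEARS | {1993, 1998}
_POUND_YEARS = _GILLNET_YEARS | {1999}
_FOODBAIT_YEARS = _SEINE_YEARS | {1989, 1993, 1996, 1998}
_EGG_YEARS = {1984} | set(range(1988, 1993)) | set(range(1994, 1998))
_FECUNDITY_YEARS = {1984} | set(range(1988, 1998))
_H1_YEARS = set(range(2005, 2010))
_H2_YEARS = set(range(1993, 2013))
_SPAWN_COMP_YEARS = set(range(1982, 2013))
_DISEASE_YEARS = set(range(1994, 2013))

# mean body weight (mt per million fish = g per fish) and eggs per female
_BASE_WEIGHT = np.array([55.0, 75.0, 95.0, 110.0, 125.0, 140.0, 155.0])
_BASE_FECUNDITY = np.array([11000.0, 15000.0, 19000.0, 22000.0, 25000.0,
                            28000.0, 31000.0])

_FLEET_WEIGHTS = {"seine": 0.55, "gillnet": 0.20, "pound": 0.10,
                  "foodbait": 0.15}

#: parameters excluded from the recovery-experiment coverage summary:
#: informed by too few years (or confounded with recruitment scale) to be
#: individually identifiable at the scenario's data density.
IDENTIFIABLE_EXCLUDE = frozenset({
    "mu9plus", "beta1", "beta2_1", "beta2_2", "mu1_1993", "mu2_1993",
    "q1", "sigma_h1"})


def default_true_parameters(grid: AgeGrid | None = None) -> ParameterVector:
    """Generating parameter vector for the default scenario."""
    grid = grid or AgeGrid()
    eta = np.log(_TRUE_RECRUITMENT[:grid.n_years])
    return ParameterVector(
        mu9plus=0.93, beta1=83.56, beta2_1=0.90, beta2_2=0.45,
        mu1_1993=0.67, mu2_1993=0.68, alpha_v=3.78, beta_v=2.27,
        q1=-0.36, sigma_h1=0.29, q2=-0.31, sigma_h2b=0.34,
        qT=float(np.log(322.58)), sigma_t=0.33, nu3=0.39, rhoM_1_4=0.80,
        rhoM_2_3=0.49, eta=eta, eta_1980_age4=6.33, eta_1980_age5=4.28)


@dataclass
class SimulationScenario:
    """Everything that defines one simulated stock and survey program."""

    grid: AgeGrid
    params: ParameterVector
    constants: FixedConstants
    exploitation: np.ndarray
    fleet_years: dict[str, set]
    fleet_weights: dict[str, float]
    d1: np.ndarray
    d2: np.ndarray
    weight: np.ndarray
    fecundity: np.ndarray
    prop_female: np.ndarray
    egg_survey_cv: float = 0.16
    pwssc_survey_cv: float = 0.10
    comp_sample_size: int = 150
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.exploitation)
        if ((e < 0) | (e > 0.95)).any():
            raise ValueError("exploitation fractions must lie in [0, 0.95]")


def _year_mask(grid: AgeGrid, years: set) -> np.ndarray:
    return np.array([y in years for y in grid.years])


def default_scenario(seed: int = 0, grid: AgeGrid | None = None
                     ) -> SimulationScenario:
    """The reference study conditions (see module docstring)."""
    grid = grid or AgeGrid()
    ny, na = grid.n_years, grid.n_ages
    params = default_true_parameters(grid)
    constants = FixedConstants()
    yrs = grid.years

    # disease covariates solved from the target mortality schedule
    d1 = np.zeros(ny)
    d2 = np.zeros(ny)
    for iy, yr in enumerate(yrs):
        if yr in _DISEASE_YEARS:
            d1[iy] = max(_M_AGE34[iy] - constants.m_base, 0.0) / params.beta1
            b2 = params.beta2_1 if yr < 2007 else params.beta2_2
            d2[iy] = max(_M_AGE58[iy] - constants.m_base, 0.0) / b2

    phase = 2.0 * np.pi * (yrs - grid.first_year)
    weight = _BASE_WEIGHT[None, :na] * (1.0 + 0.08 * np.sin(phase / 16.0)[:, None])
    fecundity = np.tile(_BASE_FECUNDITY[:na], (ny, 1))
    fecundity[~_year_mask(grid, _FECUNDITY_YEARS)] = 0.0
    prop_female = 0.5 + 0.05 * np.sin(phase / 9.0)

    masks = {
        "gillnet_caa": _year_mask(grid, _GILLNET_YEARS),
        "pound_caa": _year_mask(grid, _POUND_YEARS),
        "foodbait_caa": _year_mask(grid, _FOODBAIT_YEARS),
        "seine_comp": _year_mask(grid, _SEINE_YEARS),
        "seine_yield": _year_mask(grid, _SEINE_YEARS),
        "spawn_comp": _year_mask(grid, _SPAWN_COMP_YEARS),
        "weight": np.ones(ny, dtype=bool),
        "fecundity": _year_mask(grid, _FECUNDITY_YEARS),
        "vhsv_index": _year_mask(grid, _DISEASE_YEARS),
        "ichthyo_index": _year_mask(grid, _DISEASE_YEARS),
        "prop_female": np.ones(ny, dtype=bool),
        "eggs": _year_mask(grid, _EGG_YEARS),
        "adfg_acoustic": _year_mask(grid, _H1_YEARS),
        "pwssc_acoustic": _year_mask(grid, _H2_YEARS),
        "milt": np.ones(ny, dtype=bool),
    }
    return SimulationScenario(
        grid=grid, params=params, constants=constants,
        exploitation=_EXPLOITATION[:ny].copy(),
        fleet_years={"seine": _SEINE_YEARS, "gillnet": _GILLNET_YEARS,
                     "pound": _POUND_YEARS, "foodbait": _FOODBAIT_YEARS},
        fleet_weights=dict(_FLEET_WEIGHTS), d1=d1, d2=d2, weight=weight,
        fecundity=fecundity, prop_female=prop_female, masks=masks, seed=seed)


@dataclass
class SimulationTruth:
    """Noise-free simulated stock: state, predictions and catch/covariate data."""

    scenario: SimulationScenario
    state: PopulationState
    predicted: PredictedObservations
    data: AssessmentData   # observations set to their noise-free predictions


def _construct_catches(scenario: SimulationScenario):
    """Forward-simulate and carve fleet catches from target exploitation.

    Spring fleets remove their share of pre-fishery numbers before the first
    half-year of natural mortality; the fall food/bait fleet removes its
    share of the numbers alive before the second half.  The seine fleet is
    allocated across ages by selectivity, the others in proportion to
    abundance at ages 4+.
    """
    grid = scenario.grid
    p = scenario.params
    c = scenario.constants
    ny, na = grid.n_years, grid.n_ages
    ages = grid.ages.astype(float)
    V = selectivity(ages, p.alpha_v, p.beta_v)
    d1 = {int(y): scenario.d1[i] for i, y in enumerate(grid.years)}
    d2 = {int(y): scenario.d2[i] for i, y in enumerate(grid.years)}

    C2 = np.zeros((ny, na))
    C3 = np.zeros((ny, na))
    C4 = np.zeros((ny, na))
    seine_yield = np.zeros(ny)
    N = np.zeros(na)
    N[0] = np.exp(p.eta[0])
    N[1] = np.exp(p.eta_1980_age4)
    N[2] = np.exp(p.eta_1980_age5)
    for iy, yr in enumerate(grid.years):
        yr = int(yr)
        if iy > 0:
            N[0] = np.exp(p.eta[iy])
        active = [f for f, ys in scenario.fleet_years.items() if yr in ys]
        wsum = sum(scenario.fleet_weights[f] for f in active)
        share = {f: scenario.fleet_weights[f] / wsum for f in active} if active else {}
        e = scenario.exploitation[iy]
        total = N.sum()
        vn = V * N
        older = N.copy()
        older[0] = 0.0

        seine = np.zeros(na)
        if "seine" in share and e > 0:
            seine = e * share["seine"] * total * vn / vn.sum()
            seine_yield[iy] = float(seine @ scenario.weight[iy])
        if "gillnet" in share and e > 0:
            C2[iy] = e * share["gillnet"] * total * older / older.sum()
        if "pound" in share and e > 0:
            C3[iy] = e * share["pound"] * total * older / older.sum()

        sf = np.array([half_year_survival(yr, int(a), p, d1, d2, c.m_base,
                                          half="first", plus_age=int(ages[-1]))
                       for a in ages])
        ss = np.array([half_year_survival(yr, int(a), p, d1, d2, c.m_base,
                                          half="second", plus_age=int(ages[-1]))
                       for a in ages])
        after_a = N - (seine + C2[iy] + c.rho_k * C3[iy])
        if (after_a < 0).any():
            raise ValueError(f"infeasible scenario: spring catch exceeds "
                             f"abundance in {yr}")
        mid = after_a * sf
        if "foodbait" in share and e > 0:
            alloc = mid.copy()
            alloc[0] = 0.0
            C4[iy] = e * share["foodbait"] * mid.sum() * alloc / alloc.sum()
        after_b = mid - C4[iy]
        if (after_b < 0).any():
            raise ValueError(f"infeasible scenario: fall catch exceeds "
                             f"abundance in {yr}")
        surv = after_b * ss
        nxt = np.zeros(na)
        nxt[1:na - 1] = surv[:na - 2]
        nxt[na - 1] += surv[na - 2] + surv[na - 1]
        N = nxt
    return C2, C3, C4, seine_yield


def simulate_truth(scenario: SimulationScenario) -> SimulationTruth:
    """Run the operating model; returns the noise-free stock and data."""
    grid = scenario.grid
    ny, na = grid.n_years, grid.n_ages
    C2, C3, C4, seine_yield = _construct_catches(scenario)
    zeros_m = np.zeros((ny, na))
    data = AssessmentData(
        grid=grid, gillnet_caa=C2, pound_caa=C3, foodbait_caa=C4,
        seine_comp=zeros_m.copy(), spawn_comp=zeros_m.copy(),
        weight=scenario.weight.copy(), fecundity=scenario.fecundity.copy(),
        vhsv_index=scenario.d1.copy(), ichthyo_index=scenario.d2.copy(),
        prop_female=scenario.prop_female.copy(),
        seine_yield=seine_yield, eggs=np.zeros(ny), egg_cv=np.zeros(ny),
        adfg_acoustic=np.zeros(ny), pwssc_acoustic=np.zeros(ny),
        pwssc_cv=np.zeros(ny), milt=np.zeros(ny),
        masks={k: v.copy() for k, v in scenario.masks.items()})
    state = project_abundance(scenario.params, data, scenario.constants)
    pred = predict_observations(scenario.params, data, scenario.constants,
                                state)
    for name, series in (("seine_comp", pred.Theta1hat),
                         ("spawn_comp", pred.ThetaSphat)):
        arr = getattr(data, name)
        m = data.masks[name]
        arr[m] = series[m]
    data.eggs[data.masks["eggs"]] = pred.Ehat[data.masks["eggs"]]
    data.egg_cv[data.masks["eggs"]] = scenario.egg_survey_cv
    data.adfg_acoustic[data.masks["adfg_acoustic"]] = \
        pred.H1hat[data.masks["adfg_acoustic"]]
    data.pwssc_acoustic[data.masks["pwssc_acoustic"]] = \
        pred.H2hat[data.masks["pwssc_acoustic"]]
    data.pwssc_cv[data.masks["pwssc_acoustic"]] = scenario.pwssc_survey_cv
    data.milt[data.masks["milt"]] = pred.That[data.masks["milt"]]
    return SimulationTruth(scenario=scenario, state=state, predicted=pred,
                           data=data)


def simulate_observations(truth: SimulationTruth,
                          seed: int | None = None) -> AssessmentData:
    """Add observation noise to a noise-free simulated dataset.

    Compositions are multinomial draws at the scenario sample size; indices
    are lognormal around their predictions with the error structure the
    likelihood assumes (survey CV plus additional error in quadrature for
    eggs and the PWSSC survey; the estimated CVs for the rest), so noise is
    unbiased on the log scale.
    """
    sc = truth.scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    src = truth.data
    import copy
    data = copy.deepcopy(src)
    p = sc.params

    for name in ("seine_comp", "spawn_comp"):
        arr = getattr(data, name)
        for iy in np.flatnonzero(data.masks[name]):
            n = sc.comp_sample_size
            arr[iy] = rng.multinomial(n, np.maximum(arr[iy], 0)) / n

    def _lognoise(values, mask, sigma):
        idx = np.flatnonzero(mask)
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), values.shape)
        values[idx] *= np.exp(sig[idx] * rng.standard_normal(len(idx)))

    _lognoise(data.eggs, data.masks["eggs"],
              np.sqrt(data.egg_cv ** 2 + sc.constants.sigma_egg_extra ** 2))
    _lognoise(data.adfg_acoustic, data.masks["adfg_acoustic"], p.sigma_h1)
    _lognoise(data.pwssc_acoustic, data.masks["pwssc_acoustic"],
              np.sqrt(data.pwssc_cv ** 2 + p.sigma_h2b ** 2))
    _lognoise(data.milt, data.masks["milt"], p.sigma_t)
    return data


def recovery_experiment(scenario: SimulationScenario, fit_config: dict,
                        n_replicates: int = 20, seed: int = 0):
    """Simulate -> fit -> score coverage and bias of the generating values.

    Per replicate, observation noise is redrawn, the model is refit by
    mode-initialised MCMC, and each parameter's 95% interval is checked
    against its generating value.  Returns ``(summary, table)``: the summary
    holds average coverage over the identifiable set and the mean relative
    bias of the posterior-median recruitment scale (on the abundance scale);
    the table has per-parameter coverage and bias.
    """
    from .sampler import fit_assessment

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    truth = simulate_truth(scenario)
    theta_true = scenario.params.to_array()
    ny = scenario.grid.n_years
    names = scenario.params.layout().names
    ess = EffectiveSampleSizes(
        seine=np.full(ny, float(sc_n := scenario.comp_sample_size)),
        spawn=np.full(ny, float(sc_n)))

    cover = np.zeros((n_replicates, len(names)))
    med = np.zeros((n_replicates, len(names)))
    for r in range(n_replicates):
        data = simulate_observations(truth, seed=seed + 1000 * (r + 1))
        chain = fit_assessment(data, scenario.constants, ess,
                               seed=seed + r, **fit_config)
        lo = np.percentile(chain.draws, 2.5, axis=0)
        hi = np.percentile(chain.draws, 97.5, axis=0)
        cover[r] = (lo <= theta_true) & (theta_true <= hi)
        med[r] = np.median(chain.draws, axis=0)

    is_eta = np.array([n.startswith("eta_") for n in names])
    identifiable = np.array([n not in IDENTIFIABLE_EXCLUDE for n in names])
    # recruitment-scale bias on the abundance (exp) scale, averaged over
    # years then replicates
    rel = (np.exp(med[:, is_eta]) - np.exp(theta_true[is_eta])) \
        / np.exp(theta_true[is_eta])
    summary = {
        "coverage": float(cover[:, identifiable].mean()),
        "recruitment_bias": float(rel.mean()),
        "n_replicates": n_replicates,
        "n_identifiable": int(identifiable.sum()),
    }
    import pandas as pd
    table = pd.DataFrame({
        "parameter": names, "truth": theta_true,
        "coverage": cover.mean(axis=0),
        "median_bias": med.mean(axis=0) - theta_true,
        "identifiable": identifiable,
    })
    return summary, table
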