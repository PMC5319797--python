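"""Deterministic catch-conditioned cohort dynamics and predicted observations.

The population is tracked as pre-fishery numbers-at-age N[y, a] for ages 3
through a 9+ plus group.  Each model year runs spring removals (purse seine,
gillnet, and the lethal fraction of the pound fishery), a half year of
natural mortality, fall food/bait removals, and a second half year of
natural mortality, after which survivors age one class (Fig-4-style event
ordering: fishing before natural mortality in each half).

Natural mortality is 0.25/yr for ages 3-8 before 1992 and an estimated
total rate for the plus group; from 1992 on, disease prevalence indices
(VHSV for ages 3-4, Ichthyophonus hoferi for ages 5-8) scale additional
mortality, with dedicated estimated rates bridging 1992-93 before the
survey series begin.  The plus-group survival tracks the age-8 ratio so the
pooled class inherits the disease signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .data import AssessmentData, FixedConstants
from .params import ParameterVector

__all__ = [
    "PopulationState",
    "PredictedObservations",
    "InfeasibleParametersError",
    "selectivity",
    "purse_seine_catch_numbers",
    "spring_removals",
    "half_year_survival",
    "project_abundance",
    "predict_observations",
    "predict_acoustic",
    "predict_age_comps",
    "predict_eggs",
    "predict_milt",
]


class InfeasibleParametersError(ValueError):
    """Dynamics produced negative abundance or a degenerate state."""


@dataclass
class PopulationState:
    """Numbers-at-age and derived biomasses for one parameter vector.

    ``N`` is pre-fishery abundance (millions) over the model years;
    ``N_forecast`` the one-year-ahead survivors at ages 4+ (age-3 slot zero,
    filled by the forecast from mean recruitment).  ``S_first``/``S_second``
    are the two half-year survival schedules (they differ only in 1992).
    """

    N: np.ndarray
    N_forecast: np.ndarray
    Ntilde: np.ndarray
    B: np.ndarray
    Btilde: np.ndarray
    Btilde_post: np.ndarray
    S_first: np.ndarray
    S_second: np.ndarray
    Chat1: np.ndarray
    ChatS: np.ndarray
    maturity: np.ndarray


@dataclass
class PredictedObservations:
    """Model analogues of every fitted data stream (full-year arrays)."""

    H1hat: np.ndarray
    H2hat: np.ndarray
    Theta1hat: np.ndarray
    ThetaSphat: np.ndarray
    Ehat: np.ndarray
    That: np.ndarray


def selectivity(age, alpha_v: float, beta_v: float):
    """Logistic purse-seine selectivity; the plus group is evaluated at age 9."""
    if beta_v <= 0:
        raise ValueError("selectivity slope must be positive")
    return 1.0 / (1.0 + np.exp(-beta_v * (np.asarray(age, dtype=float) - alpha_v)))


def purse_seine_catch_numbers(yield_mt: float, comp_row: np.ndarray,
                              weight_row: np.ndarray) -> float:
    """Convert seine yield (mt) to catch in millions via predicted mean weight."""
    if yield_mt == 0:
        return 0.0
    denom = float(np.dot(comp_row, weight_row))
    if denom <= 0:
        raise InfeasibleParametersError("zero predicted mean weight with nonzero yield")
    return float(yield_mt) / denom


def spring_removals(chat1: float, comp_row: np.ndarray, gillnet_row: np.ndarray,
                    pound_row: np.ndarray, rho_k: float = 0.75) -> np.ndarray:
    """Spring removals-at-age: seine + gillnet + lethal pound fraction."""
    return np.asarray(comp_row) * chat1 + np.asarray(gillnet_row) \
        + rho_k * np.asarray(pound_row)


def half_year_survival(year: int, age: int, params: ParameterVector,
                       d1=None, d2=None, m_base: float = 0.25,
                       half: str = "second", plus_age: int = 9) -> float:
    """Half-year survival for one (year, age) cell.

    ``d1``/``d2`` map calendar year to disease prevalence (proportions); they
    are required for 1994 on.  ``half`` selects the first or second half of
    the year, which differ only in 1992 (the second half of 1992 already
    carries the estimated 1993 disease mortality).  The plus-group value uses
    the telescoped form of the age-8 ratio recursion, equivalent to updating
    year by year from the 1991 anchor.
    """
    if half not in ("first", "second"):
        raise ValueError("half must be 'first' or 'second'")

    def _m_young(yr: int, a: int) -> float:
        # ages 3-8 total M for the half-year block containing (yr, half)
        if yr <= 1991 or (yr == 1992 and half == "first"):
            return m_base
        if yr in (1992, 1993):
            return m_base + (params.mu1_1993 if a <= 4 else params.mu2_1993)
        prev = d1 if a <= 4 else d2
        if prev is None:
            raise ValueError("disease indices required for 1994-2012")
        scal = params.beta1 if a <= 4 else (
            params.beta2_1 if yr < 2007 else params.beta2_2)
        return m_base + scal * float(prev[yr])

    if age < plus_age:
        s = np.exp(-0.5 * _m_young(year, age))
    else:
        if year <= 1991:
            s = np.exp(-0.5 * params.mu9plus)
        else:
            # telescoping the ratio recursion: only the current age-8 rate
            # relative to the pre-disease background survives the product
            s = np.exp(-0.5 * (params.mu9plus + _m_young(year, 8) - m_base))
    if not 0 < s <= 1:
        raise InfeasibleParametersError(f"survival {s} outside (0, 1]")
    return float(s)


def _kernel_args(params: ParameterVector, data: AssessmentData,
                 constants: FixedConstants):
    grid = data.grid
    theta = params.to_array()
    if len(params.eta) != grid.n_years:
        raise ValueError("parameter vector year count does not match data grid")
    return (theta, grid.n_years, grid.n_ages, grid.first_year,
            data.weight, data.prop_female, data.gillnet_caa, data.pound_caa,
            data.foodbait_caa, data.seine_yield, data.vhsv_index,
            data.ichthyo_index, constants.m_base, constants.rho_k,
            constants.maturity_age4_regime2)


def project_abundance(params: ParameterVector, data: AssessmentData,
                      constants: FixedConstants | None = None) -> PopulationState:
    """Run the full cohort recursion; raise if the catches are infeasible."""
    constants = constants or FixedConstants()
    res = _kernel.run_model(*_kernel_args(params, data, constants))
    status = res[0]
    if status == 1:
        raise InfeasibleParametersError("catches exceed available abundance")
    if status != 0:
        raise InfeasibleParametersError("degenerate population state")
    _, N, Ntilde, B, Btilde, Btpost, Sf, Ss, Chat1, ChatS, _, mat = res
    return PopulationState(N=N[:-1], N_forecast=N[-1], Ntilde=Ntilde, B=B,
                           Btilde=Btilde, Btilde_post=Btpost, S_first=Sf,
                           S_second=Ss, Chat1=Chat1, ChatS=ChatS, maturity=mat)


def predict_acoustic(B: np.ndarray, q1: float, q2: float):
    """Survey-scaled biomass predictions: H_i = B * exp(q_i)."""
    B = np.asarray(B, dtype=float)
    return B * np.exp(q1), B * np.exp(q2)


def predict_age_comps(N: np.ndarray, selectivity_vector: np.ndarray,
                      maturity: np.ndarray):
    """Selectivity- and maturity-weighted age compositions (rows sum to 1)."""
    N = np.atleast_2d(np.asarray(N, dtype=float))
    vn = N * np.asarray(selectivity_vector)
    mn = N * np.atleast_2d(np.asarray(maturity))
    for arr in (vn, mn):
        if np.any(arr.sum(axis=1) <= 0):
            raise InfeasibleParametersError("all-zero composition numerator row")
    return (np.squeeze(vn / vn.sum(axis=1, keepdims=True)),
            np.squeeze(mn / mn.sum(axis=1, keepdims=True)))


def predict_eggs(Ntilde: np.ndarray, fecundity: np.ndarray,
                 prop_female: np.ndarray) -> np.ndarray:
    """Naturally spawned eggs in trillions (fecundity in eggs per female).

    Numbers are in millions of fish, so 1e-6 converts 1e12 eggs to trillions.
    """
    Ntilde = np.atleast_2d(np.asarray(Ntilde, dtype=float))
    fec = np.atleast_2d(np.asarray(fecundity, dtype=float))
    return np.squeeze(1e-6 * np.asarray(prop_female)
                      * (Ntilde * fec).sum(axis=1))


def predict_milt(Btilde_post: np.ndarray, prop_female: np.ndarray,
                 qT: float) -> np.ndarray:
    """Mile-days of milt: male post-fishery spawning biomass over exp(qT)."""
    return (1.0 - np.asarray(prop_female)) * np.asarray(Btilde_post) / np.exp(qT)


def predict_observations(params: ParameterVector, data: AssessmentData,
                         constants: FixedConstants | None = None,
                         state: PopulationState | None = None
                         ) -> PredictedObservations:
    """Model-predicted analogue of every fitted data stream."""
    constants = constants or FixedConstants()
    if state is None:
        state = project_abundance(params, data, constants)
    ages = data.grid.ages.astype(float)
    V = selectivity(ages, params.alpha_v, params.beta_v)
    th1, thsp = predict_age_comps(state.N, V, state.maturity)
    h1, h2 = predict_acoustic(state.B, params.q1, params.q2)
    ehat = predict_eggs(state.Ntilde, data.fecundity, data.prop_female)
    that = predict_milt(state.Btilde_post, data.prop_female, params.qT)
    return PredictedObservations(H1hat=h1, H2hat=h2, Theta1hat=np.atleast_2d(th1),
                                 ThetaSphat=np.atleast_2d(thsp), Ehat=ehat,
                                 That=that)
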