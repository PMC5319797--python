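"""Management-layer outputs: forecast, threshold probabilities, status table.

The management metric is mature pre-fishery ("run") biomass at the start of
the spawning season.  The fishery closes when forecast run biomass falls
below the lower regulatory threshold (22,000 short tons = 19,958 mt); a
0-0.2 harvest rate applies between the thresholds.  Per posterior draw the
model projects next-year biomass by extending the cohort recursion one year,
recruiting at the exponential of the mean log-recruitment over the previous
ten years and valuing ages with the five-year mean weight-at-age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (AssessmentData, FixedConstants, SHORT_TON_TO_MT)
from .params import ParameterVector
from .population import PopulationState

__all__ = [
    "ForecastResult",
    "forecast_next_year",
    "forecast_result",
    "prob_below_threshold",
    "exploitation_rate",
    "total_catch_mt",
    "short_tons_to_mt",
    "status_table",
]


def short_tons_to_mt(x: float) -> float:
    """Convert short tons to metric tonnes (reported rounded to whole mt)."""
    if x < 0:
        raise ValueError("tonnage must be non-negative")
    return round(x * SHORT_TON_TO_MT)


@dataclass
class ForecastResult:
    """Posterior forecast of next-year pre-fishery run biomass (mt)."""

    draws: np.ndarray
    median: float
    lo95: float
    hi95: float
    prob_below_lrt: float


def forecast_next_year(params: ParameterVector, state: PopulationState,
                       data: AssessmentData,
                       constants: FixedConstants | None = None,
                       n_recruit_years: int = 10,
                       n_weight_years: int = 5) -> float:
    """One-year-ahead pre-fishery run biomass for a single posterior draw.

    Ages 4+ come from the final-year survivors in ``state.N_forecast``; the
    age-3 contribution uses exp(mean of the last ``n_recruit_years`` log
    recruitments) (the mean deliberately ignores recruitment variability,
    understating forecast spread).  Weights are the arithmetic mean over the
    last ``n_weight_years``; maturity uses the late-regime schedule.
    """
    constants = constants or FixedConstants()
    if len(params.eta) < n_recruit_years:
        raise ValueError(f"need at least {n_recruit_years} recruitment years")
    na = data.grid.n_ages
    wbar = data.weight[-n_weight_years:].mean(axis=0)
    mat = np.ones(na)
    mat[0] = params.rhoM_2_3
    mat[1] = constants.maturity_age4_regime2
    b3 = params.rhoM_2_3 * wbar[0] * np.exp(np.mean(params.eta[-n_recruit_years:]))
    older = float(np.sum(mat[1:] * state.N_forecast[1:] * wbar[1:]))
    return float(b3 + older)


def prob_below_threshold(samples: np.ndarray, threshold: float) -> float:
    """Fraction of posterior draws strictly below the threshold."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no posterior samples")
    return float(np.mean(samples < threshold))


def forecast_result(forecast_draws: np.ndarray,
                    constants: FixedConstants | None = None) -> ForecastResult:
    constants = constants or FixedConstants()
    d = np.asarray(forecast_draws, dtype=float)
    lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
    return ForecastResult(draws=d, median=float(med), lo95=float(lo),
                          hi95=float(hi),
                          prob_below_lrt=prob_below_threshold(d, constants.lrt_mt))


def total_catch_mt(data: AssessmentData) -> np.ndarray:
    """Annual total catch in mt: seine yield plus numbers-at-age catches
    valued with the empirical weight-at-age matrix."""
    numbers = data.gillnet_caa + data.pound_caa + data.foodbait_caa
    return data.seine_yield + (numbers * data.weight).sum(axis=1)


def exploitation_rate(catch_mt: float, biomass_draws: np.ndarray):
    """Per-draw exploitation rate (catch over run biomass) with summaries.

    Returns ``(rates, median, lo95, hi95)``; non-positive biomass draws are
    excluded (they cannot arise from a feasible parameter vector).
    """
    if catch_mt < 0:
        raise ValueError("catch must be non-negative")
    b = np.asarray(biomass_draws, dtype=float)
    b = b[b > 0]
    if b.size == 0:
        raise ValueError("no positive biomass draws")
    rates = catch_mt / b
    lo, med, hi = np.percentile(rates, [2.5, 50.0, 97.5])
    return rates, float(med), float(lo), float(hi)


def _mortality_blocks(draws: np.ndarray, names: list[str],
                      data: AssessmentData, constants: FixedConstants):
    """Per-draw total non-fishery M for ages 3-4 and 5-8, by year."""
    grid = data.grid
    years = grid.years
    i = {n: j for j, n in enumerate(names)}
    m34 = np.full((draws.shape[0], grid.n_years), constants.m_base)
    m58 = m34.copy()
    for iy, yr in enumerate(years):
        if yr in (1992, 1993):
            m34[:, iy] += draws[:, i["mu1_1993"]]
            m58[:, iy] += draws[:, i["mu2_1993"]]
        elif yr >= 1994:
            m34[:, iy] += draws[:, i["beta1"]] * data.vhsv_index[iy]
            b2 = draws[:, i["beta2_1"]] if yr < 2007 else draws[:, i["beta2_2"]]
            m58[:, iy] += b2 * data.ichthyo_index[iy]
    return m34, m58


def status_table(chain, data: AssessmentData,
                 constants: FixedConstants | None = None) -> pd.DataFrame:
    """Posterior status summary by year: recruitment, run biomass, P(B<LRT),
    exploitation rate, and age-block total mortality.

    The final row is the forecast year; exploitation is blank ("--") in
    years with no recorded catch.
    """
    constants = constants or FixedConstants()
    grid = data.grid
    biomass = chain.derived["run_biomass"]
    forecast = chain.derived["forecast_biomass"]
    i = {n: j for j, n in enumerate(chain.names)}
    recruit = np.exp(chain.draws[:, [i[f"eta_{y}"] for y in grid.years]])
    catch = total_catch_mt(data)
    m34, m58 = _mortality_blocks(chain.draws, chain.names, data, constants)

    rows = []
    for iy, yr in enumerate(grid.years):
        b = biomass[:, iy]
        blo, bmed, bhi = np.percentile(b, [2.5, 50, 97.5])
        rlo, rmed, rhi = np.percentile(recruit[:, iy], [2.5, 50, 97.5])
        if catch[iy] > 0:
            _, emed, elo, ehi = exploitation_rate(catch[iy], b)
        else:
            emed = elo = ehi = np.nan
        rows.append({
            "year": yr,
            "recruit_median": rmed, "recruit_lo95": rlo, "recruit_hi95": rhi,
            "biomass_median": bmed, "biomass_lo95": blo, "biomass_hi95": bhi,
            "prob_below_lrt": prob_below_threshold(b, constants.lrt_mt),
            "exploit_median": emed, "exploit_lo95": elo, "exploit_hi95": ehi,
            "m_age34_median": float(np.median(m34[:, iy])),
            "m_age58_median": float(np.median(m58[:, iy])),
        })
    flo, fmed, fhi = np.percentile(forecast, [2.5, 50, 97.5])
    rows.append({
        "year": grid.forecast_year,
        "recruit_median": np.nan, "recruit_lo95": np.nan, "recruit_hi95": np.nan,
        "biomass_median": fmed, "biomass_lo95": flo, "biomass_hi95": fhi,
        "prob_below_lrt": prob_below_threshold(forecast, constants.lrt_mt),
        "exploit_median": np.nan, "exploit_lo95": np.nan, "exploit_hi95": np.nan,
        "m_age34_median": np.nan, "m_age58_median": np.nan,
    })
    return pd.DataFrame(rows)
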