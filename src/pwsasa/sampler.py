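"""Metropolis-Hastings sampling with single-chain convergence gates.

The production protocol is a single random-walk chain over the bounded
parameter vector, sampled on a logit-transformed unbounded scale (with the
Jacobian folded into the target) so box boundaries never reject proposals.
The proposal covariance and global step size adapt during burn-in only and
are frozen afterwards, preserving the Markov property of the retained
portion.  Convergence is accepted when every parameter's thinned-chain
lag-1 autocorrelation is below 0.10 and its Geweke z statistic (first 10%
vs last 50%, spectral-density-at-zero variance estimates) is below 1.96 in
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AssessmentData, FixedConstants
from .objective import (AssessmentObjective, EffectiveSampleSizes,
                        posterior_mode)
from .params import ParameterVector

__all__ = [
    "PosteriorChain",
    "ConvergenceReport",
    "metropolis",
    "run_mcmc",
    "geweke_z",
    "lag1_autocorrelation",
    "convergence_report",
    "fit_assessment",
]

AUTOCORR_GATE = 0.10
GEWEKE_GATE = 1.96


@dataclass
class PosteriorChain:
    """Thinned posterior draws plus per-draw derived outputs."""

    draws: np.ndarray                  # (n_kept, n_params), natural scale
    names: list[str]
    derived: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]


@dataclass
class ConvergenceReport:
    names: list[str]
    lag1: np.ndarray
    geweke: np.ndarray
    n_eff: np.ndarray
    passed: bool


def metropolis(logpdf, x0: np.ndarray, n_iter: int, seed: int = 0,
               burn_frac: float = 0.1, thin: int = 1,
               init_scale: float = 0.1, target_accept: float = 0.3,
               adapt: bool = True):
    """Adaptive random-walk Metropolis on an unconstrained target.

    Returns ``(kept_draws, acceptance_rate)``.  Covariance is learned from
    the burn-in history (scaled 2.38^2/d) with a Robbins-Monro step-size
    tuned toward ``target_accept``; both freeze when burn-in ends.  Retained
    draws are every ``thin``-th post-burn-in state, so
    ``n_iter * (1 - burn_frac) // thin`` draws come back.
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    lp0 = logpdf(x0)
    if not np.isfinite(lp0):
        raise ValueError("initial point has non-finite log density; "
                         "run a mode search first")
    rng = np.random.default_rng(seed)
    n_burn = int(n_iter * burn_frac)
    n_keep = (n_iter - n_burn) // thin
    kept = np.empty((n_keep, d))

    x, lp = x0.copy(), lp0
    log_lam = np.log(init_scale / max(np.sqrt(d), 1.0))
    chol = np.eye(d)
    mean = x.copy()
    m2 = np.zeros((d, d))
    n_acc = 0
    k = 0
    for t in range(n_iter):
        step = np.exp(log_lam) * (chol @ rng.standard_normal(d))
        xp = x + step
        lpp = logpdf(xp)
        alpha = np.exp(min(0.0, lpp - lp)) if np.isfinite(lpp) else 0.0
        if rng.random() < alpha:
            x, lp = xp, lpp
            if t >= n_burn:
                n_acc += 1
        if adapt and t < n_burn:
            # Welford running covariance of the pre-freeze history
            delta = x - mean
            mean += delta / (t + 2)
            m2 += np.outer(delta, x - mean)
            log_lam += (alpha - target_accept) / (t + 1) ** 0.6
            if t >= 200 and t % 200 == 0:
                cov = m2 / (t + 1) * (2.38 ** 2 / d)
                try:
                    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
        if t >= n_burn and (t - n_burn) % thin == thin - 1 and k < n_keep:
            kept[k] = x
            k += 1
    denom = max(n_iter - n_burn, 1)
    return kept, n_acc / denom


def run_mcmc(logpdf, init: np.ndarray, n_iter: int, burn_frac: float = 0.1,
             thin: int = 1, seed: int = 0, proposal_config: dict | None = None
             ) -> PosteriorChain:
    """Generic chain constructor around :func:`metropolis`."""
    cfg = proposal_config or {}
    draws, acc = metropolis(logpdf, init, n_iter, seed=seed,
                            burn_frac=burn_frac, thin=thin, **cfg)
    names = [f"x{i}" for i in range(draws.shape[1])]
    return PosteriorChain(draws=draws, names=names,
                          meta={"n_iter": n_iter, "burn_frac": burn_frac,
                                "thin": thin, "seed": seed,
                                "acceptance": acc})


def _spectral_density_zero(x: np.ndarray) -> float:
    """Bartlett-windowed estimate of the spectral density at frequency zero."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    K = max(int(np.sqrt(n)), 1)
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, K + 1):
        g = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (K + 1.0)) * g
    return max(s, 0.0)


def geweke_z(series: np.ndarray, first_frac: float = 0.1,
             last_frac: float = 0.5) -> float:
    """Geweke mean-equality z between the early and late chain segments.

    Segment variances use spectral-density-at-zero estimates so the implied
    effective sample sizes are autocorrelation-corrected.  Returns NaN for a
    degenerate (zero-variance) series.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 50:
        raise ValueError("series too short for the Geweke diagnostic")
    a = x[:int(first_frac * n)]
    b = x[int((1.0 - last_frac) * n):]
    va = _spectral_density_zero(a) / len(a)
    vb = _spectral_density_zero(b) / len(b)
    if va + vb <= 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def lag1_autocorrelation(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return np.nan
    return float(xc[:-1] @ xc[1:]) / denom


def _effective_n(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation-corrected sample size."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return np.nan
    rho_sum = 0.0
    for lag in range(1, n // 2):
        rho = float(xc[:-lag] @ xc[lag:]) / denom
        if rho <= 0:
            break
        rho_sum += rho
    return n / (1.0 + 2.0 * rho_sum)


def convergence_report(chain: PosteriorChain | np.ndarray,
                       names: list[str] | None = None) -> ConvergenceReport:
    """Evaluate both single-chain gates for every parameter column."""
    if isinstance(chain, PosteriorChain):
        draws, names = chain.draws, chain.names
    else:
        draws = np.asarray(chain, dtype=float)
        names = names or [f"x{i}" for i in range(draws.shape[1])]
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws")
    lag1 = np.array([lag1_autocorrelation(draws[:, j])
                     for j in range(draws.shape[1])])
    gz = np.array([geweke_z(draws[:, j]) if np.std(draws[:, j]) > 0 else np.nan
                   for j in range(draws.shape[1])])
    neff = np.array([_effective_n(draws[:, j]) for j in range(draws.shape[1])])
    ok = (np.all(np.isfinite(lag1)) and np.all(np.abs(lag1) < AUTOCORR_GATE)
          and np.all(np.isfinite(gz)) and np.all(np.abs(gz) < GEWEKE_GATE))
    return ConvergenceReport(names=list(names), lag1=lag1, geweke=gz,
                             n_eff=neff, passed=bool(ok))


def fit_assessment(data: AssessmentData,
                   constants: FixedConstants | None = None,
                   ess: EffectiveSampleSizes | None = None,
                   n_iter: int = 200_000, burn_frac: float = 0.5,
                   thin: int = 100, seed: int = 0, n_restarts: int = 4,
                   init: np.ndarray | None = None) -> PosteriorChain:
    """Mode-initialised MCMC fit returning parameters plus derived outputs.

    Derived per-draw outputs: the mature pre-fishery (run) biomass
    trajectory, the next-year biomass forecast, and the age-block total
    non-fishery mortality series.
    """
    from . import management
    from .population import project_abundance

    constants = constants or FixedConstants()
    obj = AssessmentObjective(data, constants, ess)
    layout = obj.layout
    theta0 = init if init is not None else posterior_mode(
        obj, seed=seed, n_restarts=n_restarts)
    z0 = layout.to_unbounded(theta0)
    zdraws, acc = metropolis(obj.logpost_unbounded, z0, n_iter, seed=seed,
                             burn_frac=burn_frac, thin=thin)
    draws = np.array([layout.from_unbounded(z) for z in zdraws])

    ny = data.grid.n_years
    btilde = np.empty((len(draws), ny))
    btotal = np.empty((len(draws), ny))
    forecast = np.empty(len(draws))
    for i, theta in enumerate(draws):
        pv = ParameterVector.from_array(theta, ny)
        state = project_abundance(pv, data, constants)
        btilde[i] = state.Btilde
        btotal[i] = state.B
        forecast[i] = management.forecast_next_year(pv, state, data, constants)
    chain = PosteriorChain(
        draws=draws, names=layout.names,
        derived={"run_biomass": btilde, "total_biomass": btotal,
                 "forecast_biomass": forecast},
        meta={"n_iter": n_iter, "burn_frac": burn_frac, "thin": thin,
              "seed": seed, "acceptance": acc},
    )
    return chain
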