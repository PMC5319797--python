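"""Bayesian objective: likelihood components, priors and data reweighting.

Six components enter the negative log-likelihood: two multinomial-style
age-composition terms (purse-seine catch and spawner survey, each scaled by
a per-year effective sample size), and four lognormal index terms (egg
deposition, two hydroacoustic biomass surveys, mile-days of milt).  Where a
survey supplies its own CVs (eggs, PWSSC acoustics) the total variance adds
an extra-error term in quadrature; the remaining index CVs are estimated.

All priors are uniform boxes, so the log posterior is the negative sum of
the components inside the box and -inf outside (or wherever the dynamics
are infeasible).

Composition inputs are overdispersed relative to their nominal sample sizes
(schooling, gear selectivity), so effective sample sizes are found by
McAllister-Ianelli iterative reweighting: fit the posterior mode, compute
the per-year variance-ratio sample size, shrink each series' input size by
the harmonic mean across years of estimated/input (the Stewart-Hamel
variant), and repeat to convergence.  The converged sizes are then fixed
for the MCMC run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernel
from .data import AssessmentData, FixedConstants
from .params import ParamLayout, ParameterVector, N_SCALARS

__all__ = [
    "LikelihoodBreakdown",
    "EffectiveSampleSizes",
    "AssessmentObjective",
    "comp_nll",
    "lognormal_index_nll",
    "log_prior",
    "effective_sample_size",
    "iterative_reweighting",
    "posterior_mode",
    "default_initial_point",
]

COMP_EPS = 1e-8
ESS_CAP = 500.0


@dataclass
class LikelihoodBreakdown:
    """Per-component negative log-likelihoods plus prior and posterior."""

    components: np.ndarray          # length 6
    log_prior: float
    log_posterior: float
    feasible: bool

    @property
    def total_nll(self) -> float:
        return float(self.components.sum())


@dataclass
class EffectiveSampleSizes:
    """Converged per-year ESS for the two composition series."""

    seine: np.ndarray
    spawn: np.ndarray
    trace: list = field(default_factory=list)
    converged: bool = True


def comp_nll(obs_comp: np.ndarray, pred_comp: np.ndarray, ess: np.ndarray,
             mask: np.ndarray | None = None) -> float:
    """KL-form multinomial composition term: -sum_y Z_y sum_a O log(P/O).

    Non-negative, zero iff predicted equals observed on supported cells.
    Zero-observation cells contribute nothing; predictions are floored to
    keep logs finite.
    """
    obs = np.atleast_2d(np.asarray(obs_comp, dtype=float))
    pred = np.maximum(np.atleast_2d(np.asarray(pred_comp, dtype=float)), COMP_EPS)
    ess = np.atleast_1d(np.asarray(ess, dtype=float))
    if (ess < 0).any():
        raise ValueError("effective sample sizes must be non-negative")
    if mask is None:
        mask = np.ones(obs.shape[0], dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(pred / np.where(obs > 0, obs, 1.0)), 0.0)
    return float(-(ess[mask] * terms[mask].sum(axis=1)).sum())


def lognormal_index_nll(obs: np.ndarray, pred: np.ndarray,
                        sigma_by_year: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Lognormal index term: sum_y [ln sigma_y + (ln pred - ln obs)^2 / (2 sigma_y^2)]."""
    obs = np.atleast_1d(np.asarray(obs, dtype=float))
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    sig = np.broadcast_to(np.asarray(sigma_by_year, dtype=float), obs.shape)
    if mask is None:
        mask = np.ones(obs.shape, dtype=bool)
    o, p, s = obs[mask], pred[mask], sig[mask]
    if (o <= 0).any() or (p <= 0).any():
        raise ValueError("lognormal index requires positive observations and predictions")
    if (s <= 0).any():
        raise ValueError("sigma must be positive")
    r = np.log(p) - np.log(o)
    return float(np.sum(np.log(s) + r ** 2 / (2.0 * s ** 2)))


def log_prior(params: ParameterVector | np.ndarray,
              layout: ParamLayout | None = None) -> float:
    """Flat box prior: 0 (up to a constant) inside the bounds, -inf outside."""
    if isinstance(params, ParameterVector):
        theta, layout = params.to_array(), params.layout()
    else:
        theta = np.asarray(params, dtype=float)
        layout = layout or ParamLayout(len(theta) - N_SCALARS - 2)
    return 0.0 if layout.in_bounds(theta) else -np.inf


def effective_sample_size(obs_comp: np.ndarray, pred_comp: np.ndarray,
                          cap: float = ESS_CAP) -> np.ndarray:
    """Variance-ratio effective sample size per year.

    Ratio-of-sums form: sum_a P(1-P) over sum_a (O-P)^2, capped (a perfect
    fit would otherwise diverge).
    """
    obs = np.atleast_2d(np.asarray(obs_comp, dtype=float))
    pred = np.atleast_2d(np.asarray(pred_comp, dtype=float))
    num = (pred * (1.0 - pred)).sum(axis=1)
    den = ((obs - pred) ** 2).sum(axis=1)
    with np.errstate(divide="ignore"):
        z = np.where(den > 0, num / den, np.inf)
    return np.squeeze(np.minimum(z, cap))


def _harmonic_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return len(x) / float(np.sum(1.0 / x))


class AssessmentObjective:
    """Callable log posterior for one dataset, constants and ESS set.

    Evaluations run through the compiled kernel; infeasible dynamics map to
    -inf.  ``logpost_unbounded`` adds the transform Jacobian and is the
    target handed to the sampler/optimiser.
    """

    def __init__(self, data: AssessmentData,
                 constants: FixedConstants | None = None,
                 ess: EffectiveSampleSizes | None = None):
        self.data = data
        self.constants = constants or FixedConstants()
        self.layout = ParamLayout(data.grid.n_years)
        grid = data.grid
        ny = grid.n_years
        if ess is None:
            ess = EffectiveSampleSizes(seine=np.full(ny, 150.0),
                                       spawn=np.full(ny, 150.0))
        self.ess = ess
        c = self.constants
        self._args = (ny, grid.n_ages, grid.first_year, data.weight,
                      data.prop_female, data.gillnet_caa, data.pound_caa,
                      data.foodbait_caa, data.seine_yield, data.vhsv_index,
                      data.ichthyo_index, c.m_base, c.rho_k,
                      c.maturity_age4_regime2, c.sigma_egg_extra,
                      data.fecundity, data.seine_comp,
                      data.masks["seine_comp"], data.spawn_comp,
                      data.masks["spawn_comp"], data.eggs, data.egg_cv,
                      data.masks["eggs"], data.adfg_acoustic,
                      data.masks["adfg_acoustic"], data.pwssc_acoustic,
                      data.pwssc_cv, data.masks["pwssc_acoustic"], data.milt,
                      data.masks["milt"], np.asarray(ess.seine, dtype=float),
                      np.asarray(ess.spawn, dtype=float))
        self._lo = self.layout.lower
        self._range = self.layout.upper - self._lo
        self._logrange = float(np.sum(np.log(self._range)))

    def breakdown(self, theta: np.ndarray) -> LikelihoodBreakdown:
        theta = np.asarray(theta, dtype=float)
        lp = log_prior(theta, self.layout)
        if not np.isfinite(lp):
            return LikelihoodBreakdown(np.zeros(6), -np.inf, -np.inf, False)
        status, comps = _kernel.neg_log_like(theta, *self._args)
        if status != 0:
            return LikelihoodBreakdown(np.zeros(6), lp, -np.inf, False)
        return LikelihoodBreakdown(comps, lp, -float(comps.sum()) + lp, True)

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not self.layout.in_bounds(theta):
            return -np.inf
        status, comps = _kernel.neg_log_like(theta, *self._args)
        return -float(comps.sum()) if status == 0 else -np.inf

    def logpost_unbounded(self, z: np.ndarray) -> float:
        # the transform lands strictly inside the prior box, so the box
        # check is redundant here; only dynamics feasibility can fail
        s = 1.0 / (1.0 + np.exp(-z))
        theta = self._lo + self._range * s
        status, comps = _kernel.neg_log_like(theta, *self._args)
        if status != 0:
            return -np.inf
        s = np.clip(s, 1e-300, 1.0 - 1e-16)
        jac = self._logrange + float(np.sum(np.log(s) + np.log1p(-s)))
        return -float(comps.sum()) + jac


def default_initial_point(layout: ParamLayout) -> np.ndarray:
    """Heuristic feasible starting point: mid-box scalars, moderate cohorts."""
    lo, hi = layout.lower, layout.upper
    theta = 0.5 * (lo + hi)
    pv = ParameterVector.from_array(theta, layout.n_years)
    pv.sigma_h1 = pv.sigma_h2b = pv.sigma_t = 0.30
    pv.mu9plus = 0.9
    pv.beta1 = 50.0
    pv.beta2_1 = pv.beta2_2 = 1.0
    pv.mu1_1993 = pv.mu2_1993 = 0.7
    pv.nu3 = 0.4
    pv.rhoM_1_4 = 0.8
    pv.rhoM_2_3 = 0.5
    pv.qT = 5.5
    # large initial cohorts: the catch series are fixed numbers, so a bigger
    # stock can only make the recursion more feasible as a starting point
    pv.eta = np.full(layout.n_years, 7.0)
    pv.eta_1980_age4 = 7.0
    pv.eta_1980_age5 = 6.0
    return pv.to_array()


def posterior_mode(objective: AssessmentObjective, seed: int = 0,
                   n_restarts: int = 4, init: np.ndarray | None = None,
                   maxiter: int = 500) -> np.ndarray:
    """Bounded quasi-Newton mode search with jittered restarts.

    Runs L-BFGS-B on the unbounded scale from ``n_restarts`` perturbations
    of the initial point and returns the best parameter vector found
    (natural scale).  Infeasible evaluations are given a large penalty.
    """
    layout = objective.layout
    rng = np.random.default_rng(seed)
    z0 = layout.to_unbounded(init if init is not None
                             else default_initial_point(layout))

    def negf(z):
        v = objective.logpost_unbounded(z)
        return 1e10 if not np.isfinite(v) else -v

    best_z, best_v = z0, negf(z0)
    for k in range(n_restarts):
        start = z0 if k == 0 else z0 + 0.3 * rng.standard_normal(len(z0))
        if not np.isfinite(-negf(start)) or negf(start) >= 1e10:
            continue
        res = minimize(negf, start, method="L-BFGS-B",
                       options={"maxiter": maxiter, "maxfun": 40000})
        if res.fun < best_v:
            best_z, best_v = res.x, res.fun
    return layout.from_unbounded(best_z)


def iterative_reweighting(data: AssessmentData,
                          constants: FixedConstants | None = None,
                          init_ess: float = 150.0, max_iter: int = 10,
                          tol: float = 1e-2, seed: int = 0,
                          n_restarts: int = 2,
                          cap: float = ESS_CAP) -> EffectiveSampleSizes:
    """Iteratively reweight composition sample sizes via posterior-mode fits.

    Each iteration fits the posterior mode under the current input sizes,
    computes the variance-ratio ESS per observed year, and multiplies each
    series' input size by the harmonic mean across years of the ratio of
    estimated to input size.  Stops when the relative update falls below
    ``tol``; warns (via the ``converged`` flag) otherwise.
    """
    constants = constants or FixedConstants()
    if init_ess <= 0:
        raise ValueError("initial ESS must be positive")
    ny = data.grid.n_years
    n1 = float(init_ess)
    nsp = float(init_ess)
    trace = []
    converged = False
    theta = None
    ages = data.grid.ages.astype(float)
    for it in range(max_iter):
        ess = EffectiveSampleSizes(seine=np.full(ny, n1), spawn=np.full(ny, nsp))
        obj = AssessmentObjective(data, constants, ess)
        theta = posterior_mode(obj, seed=seed + it, n_restarts=n_restarts,
                               init=theta)
        from .population import predict_age_comps, project_abundance, selectivity
        pv = ParameterVector.from_array(theta, ny)
        state = project_abundance(pv, data, constants)
        V = selectivity(ages, pv.alpha_v, pv.beta_v)
        th1, thsp = predict_age_comps(state.N, V, state.maturity)
        m1, msp = data.masks["seine_comp"], data.masks["spawn_comp"]
        raw1 = effective_sample_size(data.seine_comp[m1], th1[m1], cap)
        rawsp = effective_sample_size(data.spawn_comp[msp], thsp[msp], cap)
        r1 = _harmonic_mean(np.atleast_1d(raw1) / n1)
        rsp = _harmonic_mean(np.atleast_1d(rawsp) / nsp)
        new1, newsp = n1 * r1, nsp * rsp
        trace.append((n1, nsp, new1, newsp))
        rel = max(abs(new1 - n1) / n1, abs(newsp - nsp) / nsp)
        n1, nsp = new1, newsp
        if rel < tol:
            converged = True
            break
    return EffectiveSampleSizes(seine=np.full(ny, n1), spawn=np.full(ny, nsp),
                                trace=trace, converged=converged)
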