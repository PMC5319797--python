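# Methods

## Population dynamics

The model is a catch-conditioned statistical catch-at-age assessment for
ages 3 to a 9+ plus group over calendar years 1980–2012, with a 2013
forecast year.  Age 3 is the first age observed in numbers on the spawning
grounds; the plus group limits the influence of ageing error.  The stock is
treated as closed (no immigration or emigration).

Each model year starts at the spring spawning season.  Events are discrete
pulses, in this order: spring fishery removals (purse seine, gillnet, and
the fraction ρk = 0.75 of impounded pound-fishery fish assumed to die),
half a year of natural survival, fall food/bait removals, and the second
half year of survival, after which survivors age one class.  Spring
removals for the seine fleet are derived from observed annual yield (mt):
the predicted age composition (selectivity-weighted abundance) gives a
predicted mean weight, and yield divided by that mean weight gives catch in
millions.  Negative intermediate abundance is never clipped — it signals an
infeasible parameter vector and maps to −∞ log posterior, so the sampler
itself respects the catch-conditioning constraint.

Natural mortality:

* ages 3–8, 1980–91: fixed M = 0.25 yr⁻¹ (the lowest rate considered
  realistic for Pacific herring);
* plus group, 1980–91: estimated total rate μ9+ ∈ U(0.30, 2.00), higher
  than for younger fish on senescence grounds;
* 1992 second half and 1993: estimated additive rates μ1 (ages 3–4) and μ2
  (ages 5–8) — the collapse-era "disease" mortality, really a catch-all for
  whatever drove the 1992–93 crash, estimated because the disease surveys
  only begin in 1994;
* 1994–2012: M = 0.25 + β·d[y], where d is the VHSV prevalence (ages 3–4)
  or *I. hoferi* prevalence (ages 5–8) expressed as a proportion, and the
  β scalars are estimated; the *I. hoferi* scalar has two eras (1994–2006,
  2007–12) because the detection assay changed;
* plus group from 1992 on: survival follows the ratio of consecutive age-8
  survivals, anchored at the 1991 value — equivalently, the plus group
  carries μ9+ plus the current age-8 disease increment.

Prevalence indices are stored as proportions even though the source tables
quote percentages: the estimated scalar magnitudes are only dimensionally
consistent with proportions (e.g. a VHSV scalar near 84 with total age 3–4
mortality around 1.1 yr⁻¹ implies d ≈ 0.01).

Maturity is estimated for ages 3–4 in two regimes (1980–96 and 1997–2012,
reflecting a documented post-1997 shift), with age 5+ fully mature.  Age-3
maturity in regime 1 is parameterised as a fraction ν3 ∈ U(0, 0.75) of the
age-4 value, which keeps it strictly below age 4; regime-2 age-4 maturity
is fixed at 0.90 (estimating it drives the parameter to its bound).
Initial 1980 abundance is estimated for ages 3–5 only; ages 6+ start at
zero.  A configuration of the recruitment block estimating more 1980 ages
would be a trivial extension, but with zero initial mass the early plus
group simply fills from below within two years and the composition
likelihood floors (ε = 1e-8 inside logs) keep the first years finite.

## Likelihood and priors

Six components, summed as negative log-likelihoods over each series'
observed-year mask:

1–2. Seine and spawn-survey age compositions: multinomial KL form
−Σy Z[y] Σa Θ ln(Θ̂/Θ), with predicted compositions floored at 1e-8.
Z[y] is the effective sample size (below).  The component is Z times a KL
divergence, hence non-negative and zero only at a perfect fit.

3–6. Lognormal index terms ln σ + (ln pred − ln obs)²/(2σ²) for egg
deposition (absolute index, implied catchability 1), the two hydroacoustic
surveys (estimated log-link scalars q₁, q₂) and milt (male post-fishery
spawning biomass divided by exp(qT); the published equation typesets a
multiplication, but the definition of qT as tonnage per mile-day in log
space, and its magnitude ≈ exp(5.78) ≈ 323, require division).  Egg and
PWSSC-survey variances combine per-year survey CVs with an additional-error
term in quadrature (egg additional error fixed at 0.40; PWSSC estimated);
ADF&G acoustic and milt use single estimated CVs.  Survey CVs are treated
as the standard deviation of the log directly (asymptotic lognormal
equivalence; `cv_from_interval` derives them from 95% CIs as
ln(upper/lower)/3.92).

The leading year-count constants that appear in published renderings of
these likelihoods are the number of observed years, not multipliers; the
implementation sums over the masks.

Priors are independent uniform boxes (see `pwsasa.params` for every bound);
the log posterior is the negative likelihood sum inside the box and −∞
outside or wherever the dynamics are infeasible.

### Effective sample sizes

Raw composition sample sizes overstate their information (schooling, gear
selectivity), so input sizes are converged by iterative reweighting before
the MCMC and then fixed: fit the posterior mode under the current input
sizes, compute the variance-ratio ESS per year, Σa Θ̂(1−Θ̂) / Σa (Θ−Θ̂)²
(ratio of sums, which stays finite when a single age fits exactly; capped
at 500 because a perfect fit diverges), and multiply each series' input
size by the harmonic mean across years of estimated/input.  Defaults:
initial size 150 (the generator's multinomial sample size), tolerance 1e-2
relative, at most 10 iterations, mode-based inner fits (cheap and standard;
full MCMC per iteration would add nothing but time).

## Sampling

Single-chain random-walk Metropolis–Hastings on a logit-transformed
unbounded scale with the Jacobian folded into the target, so the uniform
box becomes a proper density and boundary rejections (e.g. maturity near 1)
never occur.  The proposal covariance is learned from the burn-in history
(scaled 2.38²/d) with a Robbins–Monro global step size tuned toward 0.3
acceptance; both freeze at the end of burn-in, preserving the Markov
property of the retained draws.  Chains are initialised at the posterior
mode found by L-BFGS-B on the unbounded scale with jittered restarts from a
deliberately large-cohort starting point (the catch series are fixed
numbers, so a larger stock is always feasible; small flat starts collide
with the big 1987 cohort's catches).

Convergence gates, applied per parameter to the thinned chain: lag-1
autocorrelation below 0.10 and |Geweke z| below 1.96, with the Geweke
segment variances estimated by Bartlett-windowed spectral density at zero
(lag window ⌊√n⌋), i.e. autocorrelation-corrected effective sample sizes.
The production preset is 11M iterations / 10% burn-in / thin 1000; the
`desk` preset (2M/10%/200) is the practical default, and tests and the
acceptance script use 2×10⁵ iterations with 50% burn-in and thin 100,
which keeps the whole verification suite in minutes while the gates — not
the iteration count — define acceptance.  At those desk scales the strict
gates are often missed on a few of the ~52 parameters; retrospective peels
therefore flag rather than discard non-passing peels by default.

Determinism: a seeded PCG64 generator drives everything; identical
(seed, config, data) reproduce chains bit for bit.

## Forecast and management outputs

Per retained draw, the cohort recursion is extended one year to get 2013
ages 4+; age-3 biomass uses exp(mean of the last ten log recruitments)
(using the mean deliberately understates forecast spread), weights are the
2008–12 arithmetic means, and maturity uses the late regime.  "Run
biomass" throughout is mature pre-fishery biomass — the spawning biomass at
the start of the season, which is what the thresholds regulate; total
biomass is also derived per draw.  Thresholds: 22,000 and 42,500 short tons
converted at 0.90718474 mt/short ton (19,958 and 38,555 mt).  Exploitation
rate is total catch in mt (seine yield plus numbers-at-age catches valued
by the weight-at-age matrix, full pound catch included since impounded fish
are removed from spawning) divided by per-draw run biomass; closed years
print a dash.

Retrospective analysis removes the terminal calendar year from every
series (shrinking the recruitment vector with it), refits, and compares the
peel's terminal-year forecast median with the full-data posterior-median
run biomass for the same calendar year; Mohn's ρ is the mean relative
difference over five peels, annotated against the (−0.22, 0.30)
rule-of-thumb band for short-lived pelagics.  Era boundaries (1992 disease
onset, 1997 maturity regime, 2007 assay change) stay at fixed calendar
years under peeling.  The background-M sensitivity refits the whole model
at M = 0.15 and 0.35 yr⁻¹: higher assumed mortality must be compensated by
larger recruitment to match the same survey biomass, raising the forecast
(on the default synthetic data: forecast medians ≈ 12.7k / 15.3k / 16.1k mt
at M = 0.15 / 0.25 / 0.35).

## Synthetic study conditions

The generator is an operating model running the same dynamics forward with
catches carved from target exploitation fractions: spring fleets take their
share of pre-fishery numbers before the first survival pulse (seine
allocated by selectivity, gillnet/pound proportional to abundance at ages
4+), food/bait takes its share of mid-year numbers.  Seine catch is stored
as yield in mt with matching age proportions so the assessment's yield
inversion is exactly consistent.

Default conditions: true parameters at realistic assessment medians
(μ9+ = 0.93, β1 = 83.56, β2 = 0.90/0.45, μ1993 = 0.67/0.68, selectivity
3.78/2.27, q₁ = −0.36, q₂ = −0.31, qT = ln 322.58, CVs 0.29/0.34/0.33,
maturity 0.39/0.80/0.49); a 33-year recruitment series with strong 1983,
1987 and 1991 cohorts and post-collapse failures; disease covariates
back-solved from a target age-block mortality history so the 1992–94
collapse and the 2003 *I. hoferi* peak appear in the data; exploitation
up to 0.22 before closure, zero from 2000 on; survey masks matching the
historical program (seine compositions 13 years, gillnet 15, pound 16,
food/bait 17, spawn compositions 31, eggs 10, ADF&G acoustics 5, PWSSC 20,
milt 33, disease indices 19).  Observation noise follows the likelihood's
own error model: multinomial compositions at sample size 150, lognormal
indices with survey CVs 0.16 (eggs) and 0.10 (PWSSC) plus the model's
additional-error terms, and the generating CVs for the single-CV indices —
so index noise is unbiased on the log scale by construction.

One deliberate deviation from the historical record: fecundity-at-age is
supplied for all egg-survey years (1984, 1988–97) rather than only through
1993, because the egg prediction needs fecundity in every fitted year; how
the original program bridged 1994–97 is not recoverable from the published
record.  Weight-at-age uses a smooth deterministic year effect (±8%)
rather than resampled empirical weights, and fecundity is
time-invariant — the generator emulates the data structure and error
model, not growth dynamics, so passing tests say nothing about
weight-driven biases in real data.

## What the tests establish (and what they don't)

A hand-unrolled 3-year × 3-age recursion pins the dynamics to 1e-12;
closed-form examples pin each likelihood component; a conjugate-normal
target calibrates the sampler against closed-form posterior moments; and
the primary surface is a 20-replicate recovery experiment at the default
conditions (2×10⁵ iterations each): average 95%-interval coverage over the
identifiable parameter set must be ≥ 90% and mean posterior-median
recruitment-scale bias below 10% (observed: ≈ 94% and ≈ 6%).  The
identifiable set excludes, a priori, parameters the default data density
cannot pin individually: μ9+, the four disease scalars and the two 1993
rates (few informative years, confounded with recruitment scale in the
collapse window — 1992–93 cohort point estimates trade off against the free
collapse mortality), and the 5-year ADF&G survey's q₁ and CV.  Coverage for
those is typically fine too (their posteriors are wide), but their point
estimates are not meaningful recovery targets.  With exactly noise-free
data the error CVs run to their lower bound and the mode is ill-posed, so
point-recovery checks use small finite noise.

All of this verifies the estimator under its own assumptions on synthetic
data; it does not validate the model against the historical observed
series, which would additionally require the archival dataset and
production-length chains.

## Numerical choices

ε = 1e-8 floor inside composition logs; ESS cap 500; reweighting tolerance
1e-2, max 10 iterations; mode search L-BFGS-B (maxiter 500, jitter 0.3 on
the unbounded scale, best of 4 restarts by default); proposal covariance
refreshed every 200 burn-in iterations with 1e-10 ridge; retention is every
`thin`-th post-burn-in state (so 10,000 iterations, 10% burn-in, thin 10
retain exactly 900 draws).  The dynamics/likelihood hot path is compiled
with numba; the first call in a fresh environment pays a one-off
compilation cost of ~20–30 s.
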