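"""Estimated parameter vector, uniform prior box and sampling transforms.

The model estimates ~17 scalar parameters (mortality, disease scalars,
selectivity, survey scalars and CVs, maturity) plus one log-recruitment per
model year and the log 1980 abundance at ages 4 and 5.  All priors are
uniform boxes; maturity at age 3 is parameterised as a fraction ``nu3`` of
the age-4 maturity so the derived age-3 proportion is always smaller.

For optimisation and MCMC the box is mapped to an unbounded scale by a
scaled-logit transform; the log-Jacobian makes the flat box prior a proper
density on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParameterVector", "ParamLayout", "scalar_bounds"]

# name -> (lower, upper) uniform prior bounds for the scalar block
_SCALAR_BOUNDS: list[tuple[str, float, float]] = [
    ("mu9plus", 0.30, 2.00),      # plus-group total M, 1980-91 (/yr)
    ("beta1", 0.00, 1000.0),      # VHSV mortality scalar, ages 3-4
    ("beta2_1", 0.00, 25.0),      # I. hoferi scalar, ages 5-8, 1994-2006
    ("beta2_2", 0.00, 25.0),      # I. hoferi scalar, ages 5-8, 2007-12
    ("mu1_1993", 0.00, 5.00),     # 1993 disease M, ages 3-4 (/yr)
    ("mu2_1993", 0.00, 5.00),     # 1993 disease M, ages 5-8 (/yr)
    ("alpha_v", 3.00, 5.00),      # seine selectivity: age at 50%
    ("beta_v", 1.00, 7.00),       # seine selectivity: slope at 50%
    ("q1", -5.00, 5.00),          # ADF&G acoustic scalar, log link
    ("sigma_h1", 0.00, 0.60),     # ADF&G acoustic CV
    ("q2", -5.00, 5.00),          # PWSSC acoustic scalar, log link
    ("sigma_h2b", 0.00, 0.60),    # PWSSC additional error
    ("qT", 2.30, 7.00),           # milt scalar, log space (mt male biomass per mile-day)
    ("sigma_t", 0.00, 0.60),      # milt CV
    ("nu3", 0.00, 0.75),          # age-3 maturity as fraction of age-4, regime 1
    ("rhoM_1_4", 0.00, 1.00),     # age-4 maturity, regime 1 (1980-96)
    ("rhoM_2_3", 0.00, 1.00),     # age-3 maturity, regime 2 (1997-)
]

_ETA_BOUNDS = (0.00, 8.01)        # log recruitment / log initial abundance

N_SCALARS = len(_SCALAR_BOUNDS)
SCALAR_NAMES = [n for n, _, _ in _SCALAR_BOUNDS]


def scalar_bounds() -> dict[str, tuple[float, float]]:
    return {n: (lo, hi) for n, lo, hi in _SCALAR_BOUNDS}


@dataclass(frozen=True)
class ParamLayout:
    """Flat-array layout for a model horizon of ``n_years`` years.

    Order: the 17 scalars, then ``eta`` (one log age-3 recruitment per model
    year, the first being the 1980 age-3 abundance), then the log 1980
    abundance at ages 4 and 5.
    """

    n_years: int

    @property
    def n_params(self) -> int:
        return N_SCALARS + self.n_years + 2

    @property
    def names(self) -> list[str]:
        first = 1980
        return (SCALAR_NAMES
                + [f"eta_{first + i}" for i in range(self.n_years)]
                + ["eta_1980_age4", "eta_1980_age5"])

    @property
    def lower(self) -> np.ndarray:
        lo = [b[1] for b in _SCALAR_BOUNDS] + [_ETA_BOUNDS[0]] * (self.n_years + 2)
        return np.array(lo)

    @property
    def upper(self) -> np.ndarray:
        hi = [b[2] for b in _SCALAR_BOUNDS] + [_ETA_BOUNDS[1]] * (self.n_years + 2)
        return np.array(hi)

    def in_bounds(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta > self.lower) and np.all(theta < self.upper))

    # --- unbounded sampling scale -------------------------------------------
    def to_unbounded(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = self.lower, self.upper
        p = (theta - lo) / (hi - lo)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p) - np.log1p(-p)

    def from_unbounded(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self.lower, self.upper
        s = 1.0 / (1.0 + np.exp(-z))
        return lo + (hi - lo) * s

    def log_jacobian(self, z: np.ndarray) -> float:
        """log |d theta / d z| of the scaled-logit map (sum over coordinates)."""
        lo, hi = self.lower, self.upper
        # log sigmoid(z) + log sigmoid(-z), numerically stable
        a = -np.logaddexp(0.0, -z)
        b = -np.logaddexp(0.0, z)
        return float(np.sum(np.log(hi - lo) + a + b))


@dataclass
class ParameterVector:
    """Named view of one point in parameter space.

    ``eta`` holds one log age-3 recruitment per model year (1980 first);
    ``eta_1980_age4``/``eta_1980_age5`` the log 1980 abundance at ages 4, 5.
    Ages 6+ in 1980 start at zero abundance.
    """

    mu9plus: float
    beta1: float
    beta2_1: float
    beta2_2: float
    mu1_1993: float
    mu2_1993: float
    alpha_v: float
    beta_v: float
    q1: float
    sigma_h1: float
    q2: float
    sigma_h2b: float
    qT: float
    sigma_t: float
    nu3: float
    rhoM_1_4: float
    rhoM_2_3: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(33))
    eta_1980_age4: float = 0.0
    eta_1980_age5: float = 0.0

    @property
    def rhoM_1_3(self) -> float:
        """Derived age-3 maturity in regime 1 (always below age-4 maturity)."""
        return self.nu3 * self.rhoM_1_4

    def to_array(self) -> np.ndarray:
        scalars = [getattr(self, n) for n in SCALAR_NAMES]
        return np.concatenate([scalars, np.asarray(self.eta, dtype=float),
                               [self.eta_1980_age4, self.eta_1980_age5]])

    @classmethod
    def from_array(cls, theta: np.ndarray, n_years: int | None = None) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        ny = (len(theta) - N_SCALARS - 2) if n_years is None else n_years
        if len(theta) != N_SCALARS + ny + 2:
            raise ValueError("array length does not match layout")
        kw = {n: float(theta[i]) for i, n in enumerate(SCALAR_NAMES)}
        return cls(eta=theta[N_SCALARS:N_SCALARS + ny].copy(),
                   eta_1980_age4=float(theta[-2]), eta_1980_age5=float(theta[-1]),
                   **kw)

    def layout(self) -> ParamLayout:
        return ParamLayout(len(self.eta))
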