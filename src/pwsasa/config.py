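"""Run configuration: a flat, documented key-value schema (YAML on disk).

Keys (all optional; defaults shown by :func:`default_config`):

``data_dir``        directory of per-series CSV files; if null, the default
                    synthetic scenario is generated with ``seed``.
``out_dir``         run output directory.
``seed``            master RNG seed for simulation, mode search and MCMC.
``preset``          MCMC preset: ``paper`` (11M iterations, 10% burn-in,
                    thin 1000), ``desk`` (2M/10%/200) or ``quick``
                    (20k/50%/10); explicit ``n_iter``/``burn_frac``/``thin``
                    override the preset.
``ess_init``, ``ess_max_iter``, ``ess_tol``   reweighting controls.
``m_base``, ``rho_k``, ``sigma_egg_extra``, ``lrt_mt``, ``urt_mt``
                    fixed-constant overrides.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .data import FixedConstants

__all__ = ["RunConfig", "load_config", "default_config", "MCMC_PRESETS"]

MCMC_PRESETS = {
    "paper": {"n_iter": 11_000_000, "burn_frac": 0.10, "thin": 1000},
    "desk": {"n_iter": 2_000_000, "burn_frac": 0.10, "thin": 200},
    "quick": {"n_iter": 20_000, "burn_frac": 0.50, "thin": 10},
}


@dataclass
class RunConfig:
    data_dir: str | None = None
    out_dir: str = "runs"
    seed: int = 0
    preset: str = "quick"
    n_iter: int | None = None
    burn_frac: float | None = None
    thin: int | None = None
    ess_init: float = 150.0
    ess_max_iter: int = 10
    ess_tol: float = 1e-2
    m_base: float | None = None
    rho_k: float | None = None
    sigma_egg_extra: float | None = None
    lrt_mt: float | None = None
    urt_mt: float | None = None

    def __post_init__(self) -> None:
        if self.preset not in MCMC_PRESETS:
            raise ValueError(f"unknown preset '{self.preset}'; "
                             f"choose from {sorted(MCMC_PRESETS)}")
        for name in ("seed", "ess_init", "ess_max_iter", "ess_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def mcmc(self) -> dict:
        cfg = dict(MCMC_PRESETS[self.preset])
        for k in ("n_iter", "burn_frac", "thin"):
            if getattr(self, k) is not None:
                cfg[k] = getattr(self, k)
        return cfg

    def constants(self) -> FixedConstants:
        base = FixedConstants()
        over = {k: getattr(self, k)
                for k in ("m_base", "rho_k", "sigma_egg_extra", "lrt_mt", "urt_mt")
                if getattr(self, k) is not None}
        return replace(base, **over)

    def digest(self) -> str:
        """Stable short hash of the configuration for stamping outputs."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
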