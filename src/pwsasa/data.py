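"""Observed-data containers, tabular I/O and variance preprocessing.

The assessment consumes seventeen tabular time series spanning 1980-2012:
three catch-at-age matrices, purse-seine yield and age composition, spawner
age composition, weight- and fecundity-at-age, proportion female, two
disease-prevalence indices, egg deposition with survey CVs, two hydroacoustic
biomass indices (one with survey CVs) and the aerial mile-days-of-milt index.
Most series have missing years; per-series boolean masks over the model years
record which rows were actually observed.

The file dialect is one delimited text file per series: first column ``year``,
remaining columns either age classes (``a3`` .. ``a9plus``) or named value
columns.  Missing years are simply absent rows; masks are inferred on load.
Disease prevalences are stored as proportions (0-1), not percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AgeGrid",
    "FixedConstants",
    "AssessmentData",
    "AssessmentDataError",
    "load_assessment_data",
    "write_assessment_data",
    "cv_from_interval",
    "weight_to_sigma",
    "SHORT_TON_TO_MT",
]

#: short tons -> metric tonnes
SHORT_TON_TO_MT = 0.90718474


@dataclass(frozen=True)
class AgeGrid:
    """Age classes 3..8 plus a 9+ group, over contiguous calendar years.

    The last age class is a plus group pooling all older fish.  The default
    grid covers 1980-2012 with a 2013 forecast year.
    """

    first_age: int = 3
    n_ages: int = 7
    first_year: int = 1980
    last_year: int = 2012

    def __post_init__(self) -> None:
        if self.n_ages < 2:
            raise ValueError("need at least one true age plus a plus group")
        if self.last_year < self.first_year:
            raise ValueError("empty year range")

    @property
    def ages(self) -> np.ndarray:
        """Numeric age of each class; the plus group evaluates at its first age."""
        return np.arange(self.first_age, self.first_age + self.n_ages)

    @property
    def age_labels(self) -> list[str]:
        labels = [str(a) for a in self.ages[:-1]]
        labels.append(f"{self.ages[-1]}+")
        return labels

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def forecast_year(self) -> int:
        return self.last_year + 1

    def year_index(self, year: int) -> int:
        if not self.first_year <= year <= self.last_year:
            raise IndexError(f"year {year} outside {self.first_year}-{self.last_year}")
        return year - self.first_year


@dataclass(frozen=True)
class FixedConstants:
    """Quantities held fixed rather than estimated.

    rho_k
        fraction of impounded (pound-fishery) herring that die, 0.75.
    m_base
        background instantaneous natural mortality for ages 3-8, 0.25 /yr.
    sigma_egg_extra
        additional lognormal error on egg deposition beyond the survey CV.
    maturity_age4_regime2
        proportion of age-4 fish mature from 1997 on, fixed at 0.90.
    lrt_mt / urt_mt
        lower/upper regulatory biomass thresholds (22,000 / 42,500 short
        tons expressed in metric tonnes).
    """

    rho_k: float = 0.75
    m_base: float = 0.25
    sigma_egg_extra: float = 0.40
    maturity_age4_regime2: float = 0.90
    lrt_mt: float = 19958.0
    urt_mt: float = 38555.0

    def __post_init__(self) -> None:
        for name in ("rho_k", "m_base", "sigma_egg_extra", "maturity_age4_regime2",
                     "lrt_mt", "urt_mt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.rho_k <= 1 or not 0 < self.maturity_age4_regime2 <= 1:
            raise ValueError("mortality/maturity fractions must be in (0, 1]")


class AssessmentDataError(ValueError):
    """Raised for missing series or validation failures on load."""


# series name -> (file name, kind); kind is "matrix" (year x age) or a list of
# value columns for year-indexed vectors
_SERIES: dict[str, tuple[str, object]] = {
    "gillnet_caa": ("gillnet_caa.csv", "matrix"),
    "pound_caa": ("pound_caa.csv", "matrix"),
    "foodbait_caa": ("foodbait_caa.csv", "matrix"),
    "seine_comp": ("seine_comp.csv", "matrix"),
    "spawn_comp": ("spawn_comp.csv", "matrix"),
    "weight": ("weight.csv", "matrix"),
    "fecundity": ("fecundity.csv", "matrix"),
    "vhsv_index": ("vhsv_index.csv", ["prevalence"]),
    "ichthyo_index": ("ichthyo_index.csv", ["prevalence"]),
    "prop_female": ("prop_female.csv", ["proportion"]),
    "seine_yield": ("seine_yield.csv", ["yield_mt"]),
    "eggs": ("eggs.csv", ["eggs_trillions", "cv"]),
    "adfg_acoustic": ("adfg_acoustic.csv", ["biomass_mt"]),
    "pwssc_acoustic": ("pwssc_acoustic.csv", ["biomass_mt", "cv"]),
    "milt": ("milt.csv", ["mile_days"]),
}

_COMP_SERIES = ("seine_comp", "spawn_comp")


@dataclass
class AssessmentData:
    """All observed series on a common age/year grid with per-series masks.

    Matrix series have shape ``(n_years, n_ages)``, vector series
    ``(n_years,)``.  Entries outside a series' mask are zero and ignored by
    the likelihood.
    """

    grid: AgeGrid
    gillnet_caa: np.ndarray
    pound_caa: np.ndarray
    foodbait_caa: np.ndarray
    seine_comp: np.ndarray
    spawn_comp: np.ndarray
    weight: np.ndarray
    fecundity: np.ndarray
    vhsv_index: np.ndarray
    ichthyo_index: np.ndarray
    prop_female: np.ndarray
    seine_yield: np.ndarray
    eggs: np.ndarray
    egg_cv: np.ndarray
    adfg_acoustic: np.ndarray
    pwssc_acoustic: np.ndarray
    pwssc_cv: np.ndarray
    milt: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ny, na = self.grid.n_years, self.grid.n_ages
        for name in _SERIES:
            arr = np.asarray(self._array_for(name), dtype=float)
            expected = (ny, na) if _SERIES[name][1] == "matrix" else (ny,)
            if arr.shape != expected:
                raise AssessmentDataError(
                    f"series '{name}' has shape {arr.shape}, expected {expected}")
            if name not in self.masks:
                self.masks[name] = np.ones(ny, dtype=bool)
            self.masks[name] = np.asarray(self.masks[name], dtype=bool)

    def _array_for(self, name: str) -> np.ndarray:
        if name == "eggs":
            return self.eggs
        if name == "pwssc_acoustic":
            return self.pwssc_acoustic
        return getattr(self, name)

    def n_observed(self, name: str) -> int:
        return int(self.masks[name].sum())

    def validate(self, comp_tol: float = 1e-3) -> None:
        """Check invariants; raise :class:`AssessmentDataError` on violation."""
        for name in _COMP_SERIES:
            comp = getattr(self, name)
            rows = comp[self.masks[name]]
            bad = np.abs(rows.sum(axis=1) - 1.0) > comp_tol
            if bad.any():
                year = self.grid.years[self.masks[name]][bad][0]
                raise AssessmentDataError(
                    f"{name} row for {year} sums to {rows.sum(axis=1)[bad][0]:.4f}, "
                    f"not 1 within {comp_tol}")
        for name in ("gillnet_caa", "pound_caa", "foodbait_caa", "seine_yield",
                     "eggs", "egg_cv", "adfg_acoustic", "pwssc_acoustic",
                     "pwssc_cv", "milt", "vhsv_index", "ichthyo_index",
                     "weight", "fecundity"):
            arr = getattr(self, name) if hasattr(self, name) else None
            if arr is not None and (np.asarray(arr) < 0).any():
                raise AssessmentDataError(f"negative values in series '{name}'")
        pf = self.prop_female[self.masks["prop_female"]]
        if ((pf < 0) | (pf > 1)).any():
            raise AssessmentDataError("prop_female outside [0, 1]")
        # fecundity must cover every fitted egg-survey year
        missing = self.masks["eggs"] & ~self.masks["fecundity"]
        if missing.any():
            year = self.grid.years[missing][0]
            raise AssessmentDataError(
                f"egg deposition fitted in {year} but no fecundity-at-age row")
        for name in ("weight", "prop_female"):
            if not self.masks[name].all():
                raise AssessmentDataError(f"series '{name}' must cover every model year")

    def truncated(self, last_year: int) -> "AssessmentData":
        """Copy with every series cut to years <= ``last_year`` (retrospective peel)."""
        if not self.grid.first_year < last_year <= self.grid.last_year:
            raise ValueError(f"last_year {last_year} outside model horizon")
        grid = AgeGrid(self.grid.first_age, self.grid.n_ages,
                       self.grid.first_year, last_year)
        n = grid.n_years

        def cut(a):
            return np.asarray(a)[:n].copy()
        return AssessmentData(
            grid=grid,
            gillnet_caa=cut(self.gillnet_caa), pound_caa=cut(self.pound_caa),
            foodbait_caa=cut(self.foodbait_caa), seine_comp=cut(self.seine_comp),
            spawn_comp=cut(self.spawn_comp), weight=cut(self.weight),
            fecundity=cut(self.fecundity), vhsv_index=cut(self.vhsv_index),
            ichthyo_index=cut(self.ichthyo_index), prop_female=cut(self.prop_female),
            seine_yield=cut(self.seine_yield), eggs=cut(self.eggs),
            egg_cv=cut(self.egg_cv), adfg_acoustic=cut(self.adfg_acoustic),
            pwssc_acoustic=cut(self.pwssc_acoustic), pwssc_cv=cut(self.pwssc_cv),
            milt=cut(self.milt),
            masks={k: cut(v) for k, v in self.masks.items()},
        )


def cv_from_interval(lower95: float, upper95: float) -> float:
    """Coefficient of variation implied by a lognormal 95% confidence interval.

    For a lognormal quantity the CV asymptotically equals the standard
    deviation of the logarithm, so sigma_log = ln(upper/lower) / (2 * 1.96).
    """
    if lower95 <= 0 or upper95 <= 0:
        raise ValueError("interval bounds must be positive")
    if upper95 < lower95:
        raise ValueError("upper bound below lower bound")
    return float(np.log(upper95 / lower95) / (2.0 * 1.96))


def weight_to_sigma(lam: float, sigma_ref: float = 0.22) -> float:
    """Lognormal standard error implied by a least-squares weight.

    Under inverse-variance weighting sigma scales as 1/sqrt(lambda); the
    anchor ``sigma_ref`` is the standard error at unit weight (0.22 for the
    milt series in the legacy weighted-least-squares model).
    """
    if lam <= 0:
        raise ValueError("weight must be positive")
    return float(sigma_ref / np.sqrt(lam))


def _read_series(path: Path, name: str, grid: AgeGrid):
    fname, kind = _SERIES[name]
    fpath = path / fname
    if not fpath.exists():
        raise AssessmentDataError(f"missing required series '{name}' ({fname})")
    df = pd.read_csv(fpath, float_precision="round_trip")
    if "year" not in df.columns:
        raise AssessmentDataError(f"series '{name}': no 'year' column")
    years = df["year"].to_numpy(dtype=int)
    inside = (years >= grid.first_year) & (years <= grid.last_year)
    df = df.loc[inside]
    years = years[inside]
    idx = years - grid.first_year
    mask = np.zeros(grid.n_years, dtype=bool)
    mask[idx] = True
    if kind == "matrix":
        cols = ["a" + lab.replace("+", "plus") for lab in grid.age_labels]
        for c in cols:
            if c not in df.columns:
                raise AssessmentDataError(f"series '{name}': missing age column '{c}'")
        out = np.zeros((grid.n_years, grid.n_ages))
        out[idx] = df[cols].to_numpy(dtype=float)
        return out, mask
    arrays = []
    for c in kind:
        if c not in df.columns:
            raise AssessmentDataError(f"series '{name}': missing column '{c}'")
        out = np.zeros(grid.n_years)
        out[idx] = df[c].to_numpy(dtype=float)
        arrays.append(out)
    return arrays, mask


def load_assessment_data(path: str | Path, grid: AgeGrid | None = None,
                         validate: bool = True) -> AssessmentData:
    """Read a directory of per-series delimited files into :class:`AssessmentData`."""
    path = Path(path)
    grid = grid or AgeGrid()
    masks: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for name in _SERIES:
        arr, mask = _read_series(path, name, grid)
        masks[name] = mask
        if name == "eggs":
            values["eggs"], values["egg_cv"] = arr
        elif name == "pwssc_acoustic":
            values["pwssc_acoustic"], values["pwssc_cv"] = arr
        elif isinstance(_SERIES[name][1], list):
            values[name] = arr[0]
        else:
            values[name] = arr
    data = AssessmentData(grid=grid, masks=masks, **values)
    if validate:
        data.validate()
    return data


def write_assessment_data(data: AssessmentData, path: str | Path) -> None:
    """Write an :class:`AssessmentData` back to the per-series file dialect."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = data.grid
    for name, (fname, kind) in _SERIES.items():
        mask = data.masks[name]
        years = grid.years[mask]
        if kind == "matrix":
            cols = ["a" + lab.replace("+", "plus") for lab in grid.age_labels]
            df = pd.DataFrame(getattr(data, name)[mask], columns=cols)
        elif name == "eggs":
            df = pd.DataFrame({"eggs_trillions": data.eggs[mask],
                               "cv": data.egg_cv[mask]})
        elif name == "pwssc_acoustic":
            df = pd.DataFrame({"biomass_mt": data.pwssc_acoustic[mask],
                               "cv": data.pwssc_cv[mask]})
        else:
            df = pd.DataFrame({kind[0]: getattr(data, name)[mask]})
            if len(kind) > 1:  # pragma: no cover - handled above
                raise AssertionError
        df.insert(0, "year", years)
        df.to_csv(path / fname, index=False, float_format="%.17g")
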