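"""Synthetic datasets with known ground truth for every pipeline stage.

The generator mirrors the fitted model: per region and release year ``t`` the
true return rate is ``R_t = exp(b0 + sum_i beta_i z_{i,t} + eps_t)`` with
``eps_t ~ N(0, noise_sd^2)`` and AR(1) standardized covariates ``z``.  Cohort
returns ``round(X_t R_t)`` are split across ages 2-5 by a baseline
age-at-return schedule (largest-remainder integerization, so cohort totals
are conserved exactly), re-aggregated by return year, and sampled by
multinomial age surveys.  Companion generators produce a seasonal-cycle-plus-
trend monthly SST grid and a lognormal species x year catch matrix with one
injected "northward-shifting predator".

All randomness derives from a single integer seed via stable sub-seeding, so
each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

_STAGE = {"covariates": 1, "noise": 2, "releases": 3, "surveys": 4,
          "sst": 5, "catch": 6}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from the single global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic life-cycle dataset.

    Defaults mirror the study: release years 1998-2019, return ages 2-5 with
    age-4 dominance, region release magnitudes of order 1.5e8 fry, and
    log-scale coefficients of the size reported for the strongest stressors.
    """

    n_regions: int = 4
    release_years: tuple[int, int] = (1998, 2019)
    ages: tuple[int, int] = (2, 5)
    true_intercept: float = math.log(0.02)
    true_betas: dict[str, float] = field(default_factory=lambda: {
        "fry_size": 0.45,
        "sst_at_release": -0.40,
        "russia_pink_t2": -0.30,
    })
    noise_sd: float = 0.3
    age_schedule: tuple[float, ...] = (0.05, 0.55, 0.35, 0.05)
    survey_sample_n: int = 200
    releases_per_year: float = 1.5e8
    exhaustive_surveys: bool = False
    ar1_rho: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.age_schedule) - 1.0) > 1e-12:
            raise ValueError("age_schedule must sum to 1 within 1e-12")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.survey_sample_n < 1:
            raise ValueError("survey_sample_n must be >= 1")
        if self.release_years[1] - self.release_years[0] + 1 < 4:
            raise ValueError("release_years must span at least 4 years")
        n_ages = self.ages[1] - self.ages[0] + 1
        if len(self.age_schedule) != n_ages:
            raise ValueError("age_schedule length must match the age range")

    @property
    def years(self) -> list[int]:
        return list(range(self.release_years[0], self.release_years[1] + 1))

    @property
    def region_names(self) -> list[str]:
        return [f"region_{i+1}" for i in range(self.n_regions)]


@dataclass
class SyntheticDataset:
    releases: pd.DataFrame        # region, release_year, fry_released
    returns: pd.DataFrame         # region, return_year, returns_total
    age_surveys: pd.DataFrame     # region, return_year, survey_id, age, proportion, sample_n
    covariates: pd.DataFrame      # region, release_year, <covariate columns>
    truth: dict                   # true betas, per-cohort true rates, labels
    sst_grid: xr.DataArray | None = None
    catch_matrix: pd.DataFrame | None = None


def _ar1_standardized(rng, n: int, rho: float) -> np.ndarray:
    """AR(1) series standardized to mean 0, SD 1 (ddof=1) over the n years."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = rho * x[i - 1] + math.sqrt(1 - rho**2) * e[i]
    return (x - x.mean()) / x.std(ddof=1)


def _largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Integerize ``total * proportions`` so the parts sum to ``total``."""
    raw = total * proportions
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def simulate_rate_panel(config: SimulationConfig, region_rng, noise_rng):
    """Covariates, noise, and true rates for one region (model-level core).

    Returns ``(z, eps, rate)``: a DataFrame of standardized AR(1) covariates
    indexed by release year, the residual vector, and the true return rates.
    Raises if any implied rate exceeds 1, naming the offending year.
    """
    years = config.years
    n = len(years)
    z = pd.DataFrame(
        {name: _ar1_standardized(region_rng, n, config.ar1_rho)
         for name in config.true_betas},
        index=pd.Index(years, name="release_year"),
    )
    eps = noise_rng.standard_normal(n) * config.noise_sd
    log_rate = (
        config.true_intercept
        + z.to_numpy() @ np.array(list(config.true_betas.values()))
        + eps
    )
    rate = np.exp(log_rate)
    if (rate > 1.0).any():
        bad = [years[i] for i in np.flatnonzero(rate > 1.0)]
        raise ValueError(
            f"implied return rate exceeds 1 in year(s) {bad}; "
            "lower true_intercept or noise_sd"
        )
    return z, eps, rate


def simulate_cohort_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset (releases, returns, surveys, truth).

    Per region and release year the true rate follows the log-linear model;
    cohort returns are integerized with exact conservation, split across ages
    by the age schedule, and re-aggregated by return year.  Age surveys are
    multinomial draws of ``survey_sample_n`` fish per return year (or exact
    compositions with the full return count when ``exhaustive_surveys``).
    """
    cov_rng = stage_rng(config.seed, "covariates")
    noise_rng = stage_rng(config.seed, "noise")
    rel_rng = stage_rng(config.seed, "releases")
    srv_rng = stage_rng(config.seed, "surveys")

    amin, amax = config.ages
    ages = list(range(amin, amax + 1))
    schedule = np.asarray(config.age_schedule, dtype=float)

    rel_rows, ret_rows, srv_rows, cov_rows = [], [], [], []
    truth: dict = {
        "true_intercept": config.true_intercept,
        "true_betas": dict(config.true_betas),
        "noise_sd": config.noise_sd,
        "regions": {},
    }
    for region in config.region_names:
        z, eps, rate = simulate_rate_panel(config, cov_rng, noise_rng)
        x = np.round(
            config.releases_per_year
            * np.exp(rel_rng.normal(0.0, 0.1, size=len(config.years)))
        ).astype(np.int64)
        age_counts: dict[int, np.ndarray] = {}
        cohort_int = np.empty(len(config.years), dtype=np.int64)
        for i, t in enumerate(config.years):
            y_t = int(round(x[i] * rate[i]))
            cohort_int[i] = y_t
            age_counts[t] = _largest_remainder(y_t, schedule)
        # aggregate by return year
        ret_years = range(config.years[0] + amin - 1, config.years[-1] + amax - 1 + 1)
        by_ry: dict[int, np.ndarray] = {
            ry: np.zeros(len(ages), dtype=np.int64) for ry in ret_years
        }
        for i, t in enumerate(config.years):
            for j, a in enumerate(ages):
                by_ry[t + a - 1][j] += age_counts[t][j]
        for i, t in enumerate(config.years):
            rel_rows.append({
                "region": region, "release_year": t, "fry_released": int(x[i]),
            })
            cov_rows.append({
                "region": region, "release_year": t,
                **{name: float(z.loc[t, name]) for name in z.columns},
            })
        for ry in ret_years:
            total = int(by_ry[ry].sum())
            ret_rows.append({
                "region": region, "return_year": ry, "returns_total": total,
            })
            if total == 0:
                continue
            mix = by_ry[ry] / total
            if config.exhaustive_surveys:
                props, n_srv = mix, total
            else:
                n_srv = config.survey_sample_n
                draw = srv_rng.multinomial(n_srv, mix)
                props = draw / n_srv
            for j, a in enumerate(ages):
                srv_rows.append({
                    "region": region, "return_year": ry, "survey_id": 1,
                    "age": a, "proportion": float(props[j]), "sample_n": n_srv,
                })
        truth["regions"][region] = {
            "release_years": config.years,
            "covariates": {c: z[c].tolist() for c in z.columns},
            "noise": eps.tolist(),
            "true_rate": rate.tolist(),
            "integerized_rate": (cohort_int / x).tolist(),
        }

    dataset = SyntheticDataset(
        releases=pd.DataFrame(rel_rows),
        returns=pd.DataFrame(ret_rows),
        age_surveys=pd.DataFrame(srv_rows),
        covariates=pd.DataFrame(cov_rows),
        truth=truth,
    )
    dataset.sst_grid = simulate_sst_grid(config)
    catch, predator = simulate_catch_matrix(config)
    dataset.catch_matrix = catch
    dataset.truth["injected_predator"] = predator
    return dataset


def simulate_sst_grid(
    config: SimulationConfig,
    lat_range: tuple[float, float] = (40.0, 60.0),
    lon_range: tuple[float, float] = (140.0, 230.0),
    resolution: float = 2.0,
    years: tuple[int, int] | None = None,
    trend: float = 0.02,
    noise_sd: float = 0.3,
    land_fraction: float = 0.05,
    climatology: np.ndarray | None = None,
) -> xr.DataArray:
    """Monthly SST grid: month climatology + linear trend x year + noise.

    The climatology is a seasonal cycle (warmest in August) with a linear
    latitude gradient; a fixed fraction of cells is masked as land (NaN for
    all months).  Years default to the release range extended to cover every
    lagged covariate window (t-1 to t+3).
    """
    if years is None:
        years = (config.release_years[0] - 1, config.release_years[1] + 3)
    if years[1] < years[0]:
        raise ValueError("empty year range for SST grid")
    rng = stage_rng(config.seed, "sst")
    lat = np.arange(lat_range[0], lat_range[1] + 1e-9, resolution)
    lon = np.arange(lon_range[0], lon_range[1] + 1e-9, resolution)
    year = np.arange(years[0], years[1] + 1)
    month = np.arange(1, 13)
    if climatology is None:
        climatology = 8.0 + 6.0 * np.cos(2 * np.pi * (month - 8) / 12.0)
    lat_gradient = -0.25 * (lat - lat.mean())
    base = (
        climatology[None, :, None, None]
        + lat_gradient[None, None, :, None]
        + trend * (year - year[0])[:, None, None, None]
    )
    noise = rng.normal(0.0, noise_sd, size=(len(year), 12, len(lat), len(lon)))
    data = np.broadcast_to(base, noise.shape) + noise
    land = rng.random((len(lat), len(lon))) < land_fraction
    data = np.where(land[None, None, :, :], np.nan, data)
    return xr.DataArray(
        data, dims=("year", "month", "lat", "lon"),
        coords={"year": year, "month": month, "lat": lat, "lon": lon},
        name="sst",
    )


def simulate_catch_matrix(
    config: SimulationConfig,
    n_species: int = 12,
    years: tuple[int, int] = (1980, 2020),
    breakpoint_year: int = 1998,
    predator_log_slope: float = 0.08,
    ar1_rho: float = 0.5,
    log_noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, str]:
    """Lognormal species x year catch matrix with one shifting predator.

    Every species follows a stationary lognormal AR(1) series around its own
    level; exactly one species additionally ramps up linearly on the log
    scale after the breakpoint year (the injected range-shifting predator).
    Returns the matrix and the true predator label.
    """
    if n_species < 3:
        raise ValueError("need >= 3 species")
    if years[1] - years[0] + 1 < 10:
        raise ValueError("need >= 10 years")
    rng = stage_rng(config.seed, "catch")
    yr = np.arange(years[0], years[1] + 1)
    species = [f"species_{i+1:02d}" for i in range(n_species)]
    predator = species[int(rng.integers(n_species))]
    rows = {}
    for sp in species:
        level = rng.uniform(math.log(1e2), math.log(1e5))
        ar = np.empty(len(yr))
        e = rng.standard_normal(len(yr)) * log_noise_sd
        ar[0] = e[0]
        for i in range(1, len(yr)):
            ar[i] = ar1_rho * ar[i - 1] + math.sqrt(1 - ar1_rho**2) * e[i]
        log_catch = level + ar
        if sp == predator:
            ramp = np.maximum(yr - breakpoint_year, 0) * predator_log_slope
            log_catch = log_catch + ramp
        rows[sp] = np.exp(log_catch)
    m = pd.DataFrame(rows, index=yr).T
    m.columns = [int(y) for y in yr]
    m.index.name = "species"
    return m, predator
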